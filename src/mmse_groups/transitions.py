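"""First/last visit pairing and group transition matrices.

Disease progression is summarised by cross-tabulating each patient's group at
the first visit (at or before the start of any medication trial) against the
group at a later visit falling 6 months to 4 years after it.  The time window
is fixed as 183–1461 days inclusive; when several follow-ups qualify the
earliest is used (minimising the time frame), configurable to the latest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .centroids import CentroidModel, classify_frame
from .errors import ValidationError
from .scoring import CATEGORIES, round_half_up
from .synthetic import GROUPS

DEFAULT_WINDOW: tuple[int, int] = (183, 1461)


@dataclass
class VisitPair:
    """A patient's first and qualifying last visit (success-rate rows)."""

    patient_id: str
    first: pd.Series
    last: pd.Series

    @property
    def gap_days(self) -> int:
        return int(self.last["visit_day"] - self.first["visit_day"])


def pair_visits(
    rates: pd.DataFrame,
    window: tuple[int, int] = DEFAULT_WINDOW,
    treatment_boundary: Optional[Mapping[str, int]] = None,
    last_rule: str = "earliest",
) -> pd.DataFrame:
    """Select one (first, last) visit pair per patient under the time-window rule.

    Parameters
    ----------
    rates:
        Success-rate table, one row per visit, with ``patient_id``,
        ``visit_day`` and the category columns.
    window:
        Inclusive (min_days, max_days) gap between first and last visit.
    treatment_boundary:
        Optional patient_id -> day; the first visit is the latest visit at or
        before that day (earliest visit overall when absent).
    last_rule:
        ``"earliest"`` (default) or ``"latest"`` qualifying follow-up.

    Returns
    -------
    One row per retained patient with columns ``patient_id, gap_days,
    first_day, last_day`` and ``first_<cat>`` / ``last_<cat>`` rate columns.
    Patients without a qualifying follow-up are dropped.
    """
    if last_rule not in ("earliest", "latest"):
        raise ValidationError(f"unknown last_rule {last_rule!r}")
    lo, hi = window
    per_patient_sorted = rates.groupby("patient_id")["visit_day"].apply(
        lambda s: s.is_monotonic_increasing
    )
    if not per_patient_sorted.all():
        # Per-patient order is what matters; sort defensively.
        warnings.warn("visit table not sorted by day; sorting internally")
    df = rates.sort_values(["patient_id", "visit_day"], kind="stable")
    rows = []
    for pid, grp in df.groupby("patient_id", sort=True):
        boundary = None
        if treatment_boundary is not None:
            boundary = treatment_boundary.get(str(pid))
        if boundary is not None:
            pre = grp.loc[grp["visit_day"] <= boundary]
            first = pre.iloc[-1] if len(pre) else grp.iloc[0]
        else:
            first = grp.iloc[0]
        gaps = grp["visit_day"] - first["visit_day"]
        qualifying = grp.loc[(gaps >= lo) & (gaps <= hi)]
        if qualifying.empty:
            continue
        last = qualifying.iloc[0] if last_rule == "earliest" else qualifying.iloc[-1]
        row = {
            "patient_id": str(pid),
            "first_day": int(first["visit_day"]),
            "last_day": int(last["visit_day"]),
            "gap_days": int(last["visit_day"] - first["visit_day"]),
        }
        for c in CATEGORIES:
            if c in grp.columns:
                row[f"first_{c}"] = float(first[c])
                row[f"last_{c}"] = float(last[c])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TransitionMatrix:
    """First-visit x last-visit group counts with row-wise proportions."""

    groups: tuple[str, ...]
    counts: pd.DataFrame  # index = first-visit group, columns = last-visit group

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def proportions(self) -> pd.DataFrame:
        """Exact row-wise percentages (rows sum to 100)."""
        totals = self.row_totals.replace(0, np.nan)
        return 100.0 * self.counts.div(totals, axis=0)

    @property
    def proportions_rounded(self) -> pd.DataFrame:
        """Display percentages, rounded half-up to integers (published layout)."""
        return self.proportions.map(
            lambda x: int(round_half_up(x, 0)) if pd.notna(x) else 0
        )

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, Mapping[str, int]], groups: Sequence[str] = GROUPS
    ) -> "TransitionMatrix":
        df = pd.DataFrame(
            [[int(counts[g].get(h, 0)) for h in groups] for g in groups],
            index=list(groups),
            columns=list(groups),
        )
        return cls(tuple(groups), df)

    @classmethod
    def from_labels(
        cls,
        pairs: Sequence[tuple[str, str]] | pd.DataFrame,
        groups: Sequence[str] = GROUPS,
    ) -> "TransitionMatrix":
        if isinstance(pairs, pd.DataFrame):
            firsts, lasts = pairs["first_group"], pairs["last_group"]
        else:
            firsts = pd.Series([a for a, _ in pairs])
            lasts = pd.Series([b for _, b in pairs])
        ct = pd.crosstab(firsts, lasts).reindex(
            index=list(groups), columns=list(groups), fill_value=0
        )
        ct.index.name = None
        ct.columns.name = None
        return cls(tuple(groups), ct)

    def to_table(self) -> pd.DataFrame:
        """Published layout: 'count (percent)' cells plus Overall row/column."""
        prop = self.proportions_rounded
        body = pd.DataFrame(
            {
                h: [f"{int(self.counts.loc[g, h])} ({int(prop.loc[g, h])})" for g in self.groups]
                for h in self.groups
            },
            index=list(self.groups),
        )
        body["Overall"] = self.row_totals.astype(int).values
        overall = {h: int(self.counts[h].sum()) for h in self.groups}
        overall["Overall"] = self.grand_total
        body.loc["Overall"] = pd.Series(overall)
        return body


def transition_matrix(
    pairs: pd.DataFrame, model: CentroidModel, groups: Sequence[str] = GROUPS
) -> TransitionMatrix:
    """Classify both ends of each visit pair with one model and tabulate transitions."""
    if pairs.empty:
        raise ValidationError("no visit pairs to tabulate")
    first = pairs[["patient_id"] + [f"first_{c}" for c in model.categories]].rename(
        columns={f"first_{c}": c for c in model.categories}
    )
    last = pairs[["patient_id"] + [f"last_{c}" for c in model.categories]].rename(
        columns={f"last_{c}": c for c in model.categories}
    )
    lab_first = classify_frame(first, model)
    lab_last = classify_frame(last, model)
    labelled = pd.DataFrame(
        {"first_group": lab_first.values, "last_group": lab_last.values}
    )
    order = [g for g in groups if g in model.groups] or list(model.groups)
    return TransitionMatrix.from_labels(labelled, groups=order)
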