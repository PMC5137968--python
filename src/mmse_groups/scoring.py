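"""MMSE scoring dialects: definition, inference from score distributions, normalization.

The mini-mental state examination (MMSE) has five categories — orientation,
registration, attention, recall and language.  Multi-trial aggregated cohorts
mix scoring *dialects*: variants of the questionnaire that assign different
maximal points per category (the standard 30-point form plus 56- and 51-point
forms).  Raw category scores from different dialects are not comparable; this
module infers which dialect a trial used from the observed score distributions
and converts raw scores to per-category *success rates* in 0–100%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import ConfigurationError, InconsistencyError, ValidationError

#: Canonical category order used everywhere in the package.
CATEGORIES: tuple[str, ...] = (
    "orientation",
    "registration",
    "attention",
    "recall",
    "language",
)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (display convention for percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ScoringSystem:
    """An MMSE dialect: per-category maximal points.

    Parameters
    ----------
    name:
        Short label, e.g. ``"mmse30"``.
    max_points:
        Mapping category -> positive integer maximum for the five categories.
    """

    name: str
    max_points: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.max_points)
        if missing:
            raise ConfigurationError(
                f"scoring system {self.name!r} missing categories: {sorted(missing)}"
            )
        if any(int(self.max_points[c]) <= 0 for c in CATEGORIES):
            raise ConfigurationError(
                f"scoring system {self.name!r} has non-positive category maxima"
            )

    @property
    def total(self) -> int:
        """Sum of the per-category maxima (the dialect's total-score scale)."""
        return int(sum(self.max_points[c] for c in CATEGORIES))

    def __hash__(self) -> int:
        return hash((self.name, tuple(self.max_points[c] for c in CATEGORIES)))


def builtin_systems() -> dict[str, ScoringSystem]:
    """The three dialects shipped with the package (30-, 56- and 51-point)."""
    raw = json.loads(
        resources.files("mmse_groups.data").joinpath("scoring_systems.json").read_text()
    )
    return {
        name: ScoringSystem(name=spec["name"], max_points=spec["max_points"])
        for name, spec in raw.items()
    }


@dataclass
class CategoryScoreRecord:
    """One MMSE administration: raw per-category points for one patient visit."""

    patient_id: str
    trial_id: str
    visit_day: int
    raw_scores: Mapping[str, int]
    total_score: Optional[int] = None

    def __post_init__(self) -> None:
        for c in CATEGORIES:
            if c not in self.raw_scores:
                raise ValidationError(
                    f"patient {self.patient_id}: missing category {c!r}"
                )
            if self.raw_scores[c] < 0:
                raise ValidationError(
                    f"patient {self.patient_id}: negative score in {c!r}"
                )


@dataclass
class SuccessRateVector:
    """Per-category performance for one visit, as percentages of the category maxima."""

    patient_id: str
    visit_day: int
    rates: Mapping[str, float] = field(default_factory=dict)


def relative_weights(system: ScoringSystem) -> dict[str, float]:
    """Relative contribution of each category to the dialect's total score, in percent.

    For the standard 30-point dialect this is (33.3, 10, 16.7, 10, 30)% for
    (orientation, registration, attention, recall, language): the weighting
    bias the multivariate analysis is designed to remove.
    """
    total = system.total
    if total <= 0:
        raise ConfigurationError(f"scoring system {system.name!r} has total {total}")
    return {c: 100.0 * system.max_points[c] / total for c in CATEGORIES}


def normalize_scores(
    record: CategoryScoreRecord, system: ScoringSystem
) -> SuccessRateVector:
    """Convert raw category points to success rates (0–100% of the category maximum)."""
    rates: dict[str, float] = {}
    for c in CATEGORIES:
        raw = record.raw_scores[c]
        mx = system.max_points[c]
        if raw > mx:
            raise ValidationError(
                f"patient {record.patient_id}: {c} score {raw} exceeds "
                f"maximum {mx} of system {system.name!r}"
            )
        rates[c] = 100.0 * raw / mx
    return SuccessRateVector(
        patient_id=record.patient_id, visit_day=record.visit_day, rates=rates
    )


def normalize_frame(
    visits: pd.DataFrame, systems: Mapping[str, ScoringSystem] | ScoringSystem
) -> pd.DataFrame:
    """Vectorised normalization of a visit table.

    Parameters
    ----------
    visits:
        Long-format table with columns ``patient_id, trial_id, visit_day`` and
        the five category columns holding raw integer scores.
    systems:
        Either a single :class:`ScoringSystem` applied to every row, or a
        mapping ``trial_id -> ScoringSystem`` (the output of
        :func:`infer_scoring_systems`).

    Returns
    -------
    DataFrame with the same identifying columns and the category columns
    replaced by success rates in percent.
    """
    out = visits.copy()
    if isinstance(systems, ScoringSystem):
        sys_of = pd.Series(
            [systems] * len(out), index=out.index, dtype=object
        )
    else:
        unknown = set(out["trial_id"]) - set(systems)
        if unknown:
            raise ValidationError(
                f"no scoring system for trials: {sorted(unknown)[:5]}"
            )
        sys_of = out["trial_id"].map(systems)
    for c in CATEGORIES:
        mx = sys_of.map(lambda s, c=c: s.max_points[c]).astype(float)
        if (out[c] > mx).any():
            bad = out.loc[out[c] > mx].iloc[0]
            raise ValidationError(
                f"patient {bad['patient_id']}: {c} score {bad[c]} exceeds "
                f"its trial's category maximum"
            )
        if (out[c] < 0).any():
            bad = out.loc[out[c] < 0].iloc[0]
            raise ValidationError(f"patient {bad['patient_id']}: negative {c} score")
        out[c] = 100.0 * out[c].astype(float) / mx
    return out


@dataclass
class SystemInference:
    """Outcome of dialect inference for one trial."""

    trial_id: str
    system: Optional[ScoringSystem]
    ambiguous: bool
    survivors: tuple[ScoringSystem, ...]


def _discriminating_categories(candidates: Iterable[ScoringSystem]) -> list[str]:
    cands = list(candidates)
    return [
        c for c in CATEGORIES if len({s.max_points[c] for s in cands}) > 1
    ]


def infer_scoring_systems(
    visits: pd.DataFrame,
    candidates: Iterable[ScoringSystem] | None = None,
    *,
    on_ambiguous: str = "exclude",
) -> dict[str, SystemInference]:
    """Infer, per trial, which scoring dialect produced the observed raw scores.

    Candidate elimination on observed per-category maxima and total-score
    consistency: a candidate survives if every observed category score is at
    or below its category maximum and every observed total at or below its
    total.  When several candidates survive, the smallest surviving system is
    selected provided some observed score *attains* its maximum in a category
    whose maxima differ among the survivors (evidence the scale tops out
    there); otherwise the trial is flagged ambiguous.

    Parameters
    ----------
    visits:
        Raw visit table (see :func:`normalize_frame`), one or more trials.
    candidates:
        Candidate dialects; defaults to the three built-in systems.
    on_ambiguous:
        ``"exclude"`` (default) leaves ambiguous trials unassigned;
        ``"fallback-30"`` assigns the standard 30-point system when it is
        among the survivors.
    """
    if on_ambiguous not in ("exclude", "fallback-30"):
        raise ConfigurationError(f"unknown ambiguity policy {on_ambiguous!r}")
    cands = list(candidates) if candidates is not None else list(builtin_systems().values())
    if not cands:
        raise ConfigurationError("candidate set is empty")

    results: dict[str, SystemInference] = {}
    for trial_id, grp in visits.groupby("trial_id", sort=True):
        obs_max = {c: int(grp[c].max()) for c in CATEGORIES}
        totals = grp["total"].dropna() if "total" in grp else pd.Series(dtype=float)
        obs_total_max = int(totals.max()) if len(totals) else 0

        survivors = [
            s
            for s in cands
            if all(obs_max[c] <= s.max_points[c] for c in CATEGORIES)
            and obs_total_max <= s.total
        ]
        if not survivors:
            raise InconsistencyError(
                f"trial {trial_id!r}: observed maxima {obs_max} fit no candidate system"
            )
        if len(survivors) == 1:
            results[str(trial_id)] = SystemInference(
                str(trial_id), survivors[0], False, tuple(survivors)
            )
            continue

        survivors.sort(key=lambda s: (s.total, s.name))
        smallest = survivors[0]
        disc = _discriminating_categories(survivors)
        attained = any(obs_max[c] == smallest.max_points[c] for c in disc)
        if attained:
            results[str(trial_id)] = SystemInference(
                str(trial_id), smallest, False, tuple(survivors)
            )
        else:
            fallback = None
            if on_ambiguous == "fallback-30":
                fallback = next((s for s in survivors if s.total == 30), None)
            results[str(trial_id)] = SystemInference(
                str(trial_id), fallback, True, tuple(survivors)
            )
    return results


def read_visits_csv(path) -> pd.DataFrame:
    """Read the long-format visit CSV (patient_id, trial_id, visit_day, five categories, total)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "trial_id": str})
    required = {"patient_id", "trial_id", "visit_day", *CATEGORIES}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"visit CSV missing columns: {sorted(missing)}")
    return df
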