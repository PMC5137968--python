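"""Signature categories, group centroids, nearest-centroid classification, agreement.

The classifier is deliberately simple: each group is represented by the mean
success-rate vector (its *centroid*) over the categories that discriminate
groups the most, and a patient is assigned to the group with the nearest
centroid in Euclidean distance.  Category selection uses the Kruskal–Wallis
rank test per category; with five groups of ~hundreds of patients the
interesting p-values underflow double precision, so tail probabilities are
also carried in log10 space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import ValidationError
from .scoring import CATEGORIES
from .synthetic import GROUPS


@dataclass
class CentroidModel:
    """Per-group mean success rates over the selected categories."""

    categories: tuple[str, ...]
    centroids: dict[str, dict[str, float]]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.categories = tuple(self.categories)
        for g, cent in self.centroids.items():
            missing = set(self.categories) - set(cent)
            if missing:
                raise ValidationError(f"centroid {g!r} missing categories {sorted(missing)}")
            for c in self.categories:
                if not 0.0 <= cent[c] <= 100.0:
                    raise ValidationError(f"centroid {g!r}/{c} outside [0, 100]")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(self.centroids)

    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.centroids[g][c] for c in self.categories] for g in self.groups]
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "categories": list(self.categories),
                    "centroids": self.centroids,
                    "provenance": self.provenance,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CentroidModel":
        raw = json.loads(Path(path).read_text())
        return cls(
            categories=tuple(raw["categories"]),
            centroids={g: dict(v) for g, v in raw["centroids"].items()},
            provenance=raw.get("provenance", ""),
        )


def paper_model() -> CentroidModel:
    """The packaged published signature (registration/attention/recall centroids)."""
    raw = json.loads(
        resources.files("mmse_groups.data").joinpath("table1_centroids.json").read_text()
    )
    return CentroidModel(
        categories=tuple(raw["categories"]),
        centroids={g: dict(v) for g, v in raw["centroids"].items()},
        provenance=raw["provenance"],
    )


@dataclass
class KWResult:
    """Kruskal–Wallis outcome for one category."""

    statistic: float
    pvalue: float
    log10_pvalue: float


def chi2_log10_sf(x: float, df: int) -> float:
    """log10 of the chi-square upper tail, finite for arbitrarily large x.

    scipy's logsf underflows to -inf once sf drops past the subnormal range
    (H beyond ~1550 at df 4); there the standard asymptotic expansion
    sf(x) ~ (x/2)^(df/2-1) e^(-x/2) / Gamma(df/2) * (1 + (df/2-1)/(x/2))
    takes over, with relative error O(x^-2).
    """
    val = float(stats.chi2.logsf(x, df))
    if np.isfinite(val):
        return val / np.log(10.0)
    h = x / 2.0
    a = df / 2.0
    log_sf = -h + (a - 1.0) * np.log(h) - float(gammaln(a)) + np.log1p((a - 1.0) / h)
    return float(log_sf / np.log(10.0))


def kruskal_wallis_by_category(
    rates: pd.DataFrame,
    labels: Mapping[str, object] | pd.Series,
    categories: Sequence[str] = CATEGORIES,
) -> dict[str, KWResult]:
    """Per-category Kruskal–Wallis H (tie-corrected) across the labelled groups.

    ``rates`` holds one row per patient with a ``patient_id`` column; ``labels``
    maps patient_id to group.  p-values use the chi-square approximation with
    df = groups - 1; ``log10_pvalue`` is computed via the log survival
    function and stays finite where ``pvalue`` underflows to zero.
    """
    lab = pd.Series(labels)
    lab.index = lab.index.astype(str)
    df = rates.copy()
    df["__group"] = df["patient_id"].astype(str).map(lab)
    if df["__group"].isna().any():
        raise ValidationError("some patients have no group label")
    group_names = sorted(df["__group"].unique())
    if len(group_names) < 2:
        raise ValidationError("Kruskal–Wallis needs at least two groups")
    out: dict[str, KWResult] = {}
    dof = len(group_names) - 1
    for c in categories:
        samples = [df.loc[df["__group"] == g, c].to_numpy(dtype=float) for g in group_names]
        if any(len(s) == 0 for s in samples):
            raise ValidationError(f"empty group in category {c!r}")
        values = np.concatenate(samples)
        if np.all(values == values[0]):
            out[c] = KWResult(0.0, 1.0, 0.0)
            continue
        H, _ = stats.kruskal(*samples)
        p = float(stats.chi2.sf(H, dof))
        out[c] = KWResult(float(H), p, chi2_log10_sf(float(H), dof))
    return out


def select_categories(
    kw: Mapping[str, float | KWResult], n_keep: int
) -> tuple[str, ...]:
    """The ``n_keep`` categories with smallest p-values.

    Accepts raw p-values or :class:`KWResult` objects (whose log10 p-value is
    used, immune to underflow ties at zero).  Order: ascending p-value; ties
    broken by canonical category order.
    """
    if n_keep > len(kw):
        raise ValidationError(f"n_keep={n_keep} exceeds {len(kw)} categories")

    def key(c: str) -> tuple[float, int]:
        v = kw[c]
        p = v.log10_pvalue if isinstance(v, KWResult) else float(v)
        return (p, CATEGORIES.index(c) if c in CATEGORIES else len(CATEGORIES))

    ranked = sorted(kw, key=key)
    return tuple(ranked[:n_keep])


def compute_centroids(
    rates: pd.DataFrame,
    labels: Mapping[str, object] | pd.Series,
    categories: Sequence[str],
    provenance: str = "",
) -> CentroidModel:
    """Arithmetic mean success rate per group over the selected categories."""
    lab = pd.Series(labels)
    lab.index = lab.index.astype(str)
    df = rates.copy()
    df["__group"] = df["patient_id"].astype(str).map(lab)
    if df["__group"].isna().any():
        raise ValidationError("some patients have no group label")
    declared = set(lab.values)  # a declared group with no rows is an error
    if declared <= set(GROUPS):
        groups = [g for g in GROUPS if g in declared]  # canonical best-to-worst order
    else:
        groups = sorted(declared, key=str)
    centroids: dict[str, dict[str, float]] = {}
    for g in groups:
        sub = df.loc[df["__group"] == g]
        if sub.empty:
            raise ValidationError(f"group {g!r} has no members")
        centroids[str(g)] = {c: float(sub[c].mean()) for c in categories}
    return CentroidModel(tuple(categories), centroids, provenance=provenance)


def classify(
    rates: Mapping[str, float], model: CentroidModel
) -> tuple[str, dict[str, float]]:
    """Nearest-centroid assignment for a single success-rate vector.

    Returns the winning group and the distance to every centroid.  Ties are
    broken by the model's group order (best group first in the packaged model).
    """
    missing = set(model.categories) - set(rates)
    if missing:
        raise ValidationError(f"rates vector missing categories: {sorted(missing)}")
    x = np.array([rates[c] for c in model.categories], dtype=float)
    dists = {
        g: float(np.linalg.norm(x - np.array([model.centroids[g][c] for c in model.categories])))
        for g in model.groups
    }
    best = min(model.groups, key=lambda g: dists[g])  # min is stable: first minimal wins
    return best, dists


def classify_frame(rates: pd.DataFrame, model: CentroidModel) -> pd.Series:
    """Vectorised nearest-centroid assignment; index = patient_id."""
    missing = set(model.categories) - set(rates.columns)
    if missing:
        raise ValidationError(f"rates table missing categories: {sorted(missing)}")
    X = rates.loc[:, list(model.categories)].to_numpy(dtype=float)
    C = model.matrix()
    d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
    idx = d2.argmin(axis=1)  # argmin takes the first minimum: model group order
    groups = np.array(model.groups, dtype=object)
    return pd.Series(groups[idx], index=rates["patient_id"].astype(str), name="group")


@dataclass
class AgreementResult:
    """Two-rater agreement over nominal group labels."""

    percent_agreement: float
    kappa: float
    n: int
    confusion: pd.DataFrame


def fleiss_kappa_two_raters(
    labels_a: pd.Series, labels_b: pd.Series, categories: Sequence[str]
) -> float:
    """Fleiss' kappa for exactly two raters.

    With n=2 raters the per-subject agreement P_i is 1 when the raters agree
    and 0 otherwise, so P-bar is the raw agreement fraction; chance agreement
    P-bar_e is the sum of squared pooled category proportions.
    """
    n = len(labels_a)
    p_bar = float((labels_a.values == labels_b.values).mean())
    pooled = pd.concat([labels_a, labels_b], ignore_index=True)
    p_j = pooled.value_counts(normalize=True).reindex(categories, fill_value=0.0)
    p_e = float((p_j**2).sum())
    if p_e >= 1.0:
        # Single category used by both raters: agreement carries no information.
        return 1.0 if p_bar == 1.0 else float("nan")
    return (p_bar - p_e) / (1.0 - p_e)


def agreement(
    labels_a: Mapping[str, object] | pd.Series,
    labels_b: Mapping[str, object] | pd.Series,
    categories: Sequence[str] = GROUPS,
) -> AgreementResult:
    """Percentage agreement and Fleiss' kappa between two label assignments."""
    a = pd.Series(labels_a).astype(str)
    b = pd.Series(labels_b).astype(str)
    a.index = a.index.astype(str)
    b.index = b.index.astype(str)
    if len(a) == 0:
        raise ValidationError("empty label sets")
    if set(a.index) != set(b.index):
        raise ValidationError("label sets cover different patients")
    b = b.reindex(a.index)
    cats = [str(c) for c in categories]
    extra = sorted((set(a) | set(b)) - set(cats))
    cats = cats + extra
    confusion = pd.crosstab(a, b).reindex(index=cats, columns=cats, fill_value=0)
    pct = 100.0 * float(np.diag(confusion.to_numpy()).sum()) / len(a)
    kappa = fleiss_kappa_two_raters(a, b, cats)
    return AgreementResult(pct, kappa, len(a), confusion)
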