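"""Euclidean distances over success-rate vectors and Ward hierarchical clustering.

Patients are points in category space (each coordinate a success rate in
0–100%), compared with the ordinary Euclidean metric; with five categories
distances lie in [0, 100·sqrt(5)] ≈ [0, 223.6].  Groups are defined by Ward
agglomerative clustering — each merge is the one minimising the increase in
total within-cluster variance.  On Euclidean input this is the "ward.D2"
criterion, the variant that genuinely minimises within-cluster variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from .errors import ValidationError
from .scoring import CATEGORIES, SuccessRateVector


def euclidean_distance(
    p: SuccessRateVector | Mapping[str, float],
    q: SuccessRateVector | Mapping[str, float],
    categories: Sequence[str] = CATEGORIES,
) -> float:
    """Euclidean distance between two success-rate vectors over the given categories."""
    pr = p.rates if isinstance(p, SuccessRateVector) else p
    qr = q.rates if isinstance(q, SuccessRateVector) else q
    for name, r in (("p", pr), ("q", qr)):
        missing = set(categories) - set(r)
        if missing:
            raise ValidationError(f"vector {name} missing categories: {sorted(missing)}")
    a = np.array([pr[c] for c in categories], dtype=float)
    b = np.array([qr[c] for c in categories], dtype=float)
    return float(np.linalg.norm(a - b))


@dataclass
class DistanceMatrix:
    """Pairwise Euclidean distances between patients (percent units)."""

    ids: tuple[str, ...]
    condensed: np.ndarray  # scipy condensed form, length n*(n-1)/2

    @property
    def square(self) -> np.ndarray:
        return squareform(self.condensed)

    def __len__(self) -> int:
        return len(self.ids)


def distance_matrix(
    rates: pd.DataFrame, categories: Sequence[str] = CATEGORIES
) -> DistanceMatrix:
    """Distance matrix from a rates table (one row per patient).

    ``rates`` must carry a ``patient_id`` column plus the category columns.
    """
    missing = set(categories) - set(rates.columns)
    if missing:
        raise ValidationError(f"rates table missing categories: {sorted(missing)}")
    ids = tuple(str(x) for x in rates["patient_id"])
    X = rates.loc[:, list(categories)].to_numpy(dtype=float)
    return DistanceMatrix(ids=ids, condensed=pdist(X, metric="euclidean"))


@dataclass
class ClusteringResult:
    """Cut dendrogram: cluster labels per patient plus the merge history."""

    labels: dict[str, int]
    k: int
    merge_history: np.ndarray  # scipy linkage matrix (n-1) x 4

    def label_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster")


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 by order of first appearance (row-order canonical)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, v in enumerate(raw):
        if v not in mapping:
            mapping[v] = len(mapping)
        out[i] = mapping[v]
    return out


def ward_cluster(dm: DistanceMatrix, k: int) -> ClusteringResult:
    """Agglomerate under the Ward minimum-variance objective and cut at ``k`` clusters."""
    n = len(dm)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range for {n} samples")
    Z = linkage(dm.condensed, method="ward")
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels = _canonical_labels(raw)
    if len(np.unique(labels)) != k:
        # Exact ties can make maxclust undershoot; force the cut by merge order.
        raw = fcluster(Z, t=Z[-(k - 1), 2] - 1e-9 if k > 1 else Z[-1, 2] + 1, criterion="distance")
        labels = _canonical_labels(raw)
    return ClusteringResult(
        labels={pid: int(l) for pid, l in zip(dm.ids, labels)},
        k=int(len(np.unique(labels))),
        merge_history=Z,
    )


def within_cluster_variance(dm_square: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared deviations from cluster means.

    Computed from pairwise distances: for each cluster,
    sum_{i<j} d(i,j)^2 / n_cluster — identical to the sum of squared
    deviations from the centroid when distances are Euclidean.
    """
    total = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < 2:
            continue
        sub = dm_square[np.ix_(idx, idx)]
        total += float((sub**2).sum()) / (2.0 * len(idx))
    return total


def select_k(dm: DistanceMatrix, k_range: Sequence[int]) -> tuple[int, pd.DataFrame]:
    """Diagnostics for choosing the cluster count.

    Returns the silhouette-maximising k in ``k_range`` together with a
    per-k table of total within-cluster variance and mean silhouette.  With a
    degenerate (all-zero) distance matrix a single cluster is returned with a
    warning.  The replication pipeline fixes k=5; this is diagnostic only.
    """
    n = len(dm)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    square = dm.square
    if np.allclose(dm.condensed, 0.0):
        warnings.warn("degenerate distance matrix (all zeros); returning k=1")
        return 1, pd.DataFrame({"k": [1], "within_var": [0.0], "silhouette": [np.nan]})
    rows = []
    for k in ks:
        res = ward_cluster(dm, k)
        labels = np.array([res.labels[pid] for pid in dm.ids])
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(square, labels, metric="precomputed"))
        rows.append(
            {"k": k, "within_var": within_cluster_variance(square, labels), "silhouette": sil}
        )
    if not rows:
        warnings.warn("no valid k in range; returning k=1")
        return 1, pd.DataFrame({"k": [1], "within_var": [0.0], "silhouette": [np.nan]})
    diag = pd.DataFrame(rows)
    best = int(diag.loc[diag["silhouette"].idxmax(), "k"])
    return best, diag
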