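"""Chemometric stage: z-scoring, PCA, Ward hierarchical clustering.

The clustering convention is the plain objective-increase form of Ward's
criterion: at every step the pair of clusters minimizing

    ΔESS(A, B) = |A||B| / (|A| + |B|) · ‖centroid(A) − centroid(B)‖²

is merged, and the merge height recorded is ΔESS itself.  Conventions
differ between packages — scipy's ``ward`` linkage reports
``sqrt(2·ΔESS)`` — so the dendrogram exposes both scales.  Ties break
deterministically toward the lexicographically smallest cluster-id pair.

z-scoring uses the population (divide-by-n) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PCAResult",
    "Dendrogram",
    "zscore",
    "pca",
    "ward_hca",
    "cut_clusters",
]


def _as_matrix(table) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(table, pd.DataFrame):
        return table.to_numpy(float), [str(i) for i in table.index], [str(c) for c in table.columns]
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    return x, [str(i) for i in range(x.shape[0])], [str(j) for j in range(x.shape[1])]


def zscore(table):
    """Standardize columns to mean 0 and population standard deviation 1.

    Accepts a DataFrame or array and returns the same type.  A constant
    (zero-variance) column is an error.
    """
    x, _, cols = _as_matrix(table)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population (ddof=0)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        raise ValueError(f"constant column(s) cannot be z-scored: {[cols[j] for j in bad]}")
    z = (x - mean) / sd
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(z, index=table.index, columns=table.columns)
    return z


@dataclass
class PCAResult:
    """Principal components of a (standardized) data matrix.

    ``loadings`` columns are orthonormal eigenvectors of the covariance
    (divide-by-n) of the centered data, sorted by decreasing eigenvalue,
    with each column's largest-magnitude entry made positive;
    ``scores = centered data @ loadings``.
    """

    loadings: np.ndarray                 # features x components
    scores: np.ndarray                   # samples x components
    explained_variance_ratio: np.ndarray
    eigenvalues: np.ndarray
    feature_names: list[str]
    sample_names: list[str]

    def scores_frame(self, n_components: int = 2) -> pd.DataFrame:
        k = min(n_components, self.scores.shape[1])
        return pd.DataFrame(
            self.scores[:, :k],
            index=self.sample_names,
            columns=[f"PC{i + 1}" for i in range(k)],
        )


def pca(matrix) -> PCAResult:
    """Full PCA by eigendecomposition of the covariance matrix.

    On z-scored input the covariance equals the correlation matrix.  The
    input is centered (a no-op for z-scored data) so scores always have
    zero column means.
    """
    x, rows, cols = _as_matrix(matrix)
    n = x.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least two rows")
    if not np.all(np.isfinite(x)):
        raise ValueError("PCA input contains missing/non-finite values")
    xc = x - x.mean(axis=0)
    cov = xc.T @ xc / n
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    for j in range(v.shape[1]):
        k = int(np.argmax(np.abs(v[:, j])))
        if v[k, j] < 0:
            v[:, j] = -v[:, j]
    total = w.sum()
    ratio = w / total if total > 0 else np.zeros_like(w)
    return PCAResult(
        loadings=v,
        scores=xc @ v,
        explained_variance_ratio=ratio,
        eigenvalues=w,
        feature_names=cols,
        sample_names=rows,
    )


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy-style id numbering.

    Row ``t`` of ``merges`` is ``(id_a, id_b, height, size)``: clusters
    ``id_a < id_b`` merged at step ``t`` into new cluster ``n + t``.
    Ids below ``n`` are leaves.  ``height`` is the Ward objective
    increase ΔESS of the merge.
    """

    merges: np.ndarray       # (n-1, 4)
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_scipy_linkage(self) -> np.ndarray:
        """Linkage matrix on scipy's Ward.D2 height scale sqrt(2·ΔESS)."""
        z = self.merges.copy()
        z[:, 2] = np.sqrt(2.0 * np.clip(z[:, 2], 0.0, None))
        return z

    def to_records(self) -> list[dict]:
        return [
            {"a": int(a), "b": int(b), "height": float(h), "size": int(s)}
            for a, b, h, s in self.merges
        ]


def ward_hca(matrix, labels: Sequence[str] | None = None) -> Dendrogram:
    """Agglomerative clustering under Ward's minimum-variance criterion.

    Cluster centroids are recomputed from member rows at every step, so
    heights are exact ΔESS values; duplicate rows simply merge at height
    zero.  Deterministic: equal ΔESS ties go to the smallest (a, b) id
    pair.
    """
    x, rows, _ = _as_matrix(matrix)
    n = x.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least two rows")
    if labels is None:
        labels = rows
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = np.zeros((n - 1, 4))
    for t in range(n - 1):
        active = sorted(members)
        centroid = {c: x[members[c]].mean(axis=0) for c in active}
        best = None
        for a, b in combinations(active, 2):
            na, nb = len(members[a]), len(members[b])
            diff = centroid[a] - centroid[b]
            d = na * nb / (na + nb) * float(diff @ diff)
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        new = n + t
        members[new] = members.pop(a) + members.pop(b)
        merges[t] = (a, b, d, len(members[new]))
    return Dendrogram(merges=merges, labels=list(labels))


def cut_clusters(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Flat ``k``-cluster labels obtained by undoing the last ``k − 1`` merges.

    Labels are integers ``0 .. k−1``, numbered by first leaf occurrence,
    so the assignment is stable across runs.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = {}
    for t in range(n - k):
        a, b = int(dendrogram.merges[t, 0]), int(dendrogram.merges[t, 1])
        parent[a] = parent[b] = n + t

    def root(i: int) -> int:
        while i in parent:
            i = parent[i]
        return i

    labels = np.empty(n, dtype=int)
    seen: dict[int, int] = {}
    for leaf in range(n):
        r = root(leaf)
        if r not in seen:
            seen[r] = len(seen)
        labels[leaf] = seen[r]
    return labels
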