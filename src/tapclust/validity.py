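"""Cluster-count diagnostics: inertia/elbow, silhouette, and Davies-Bouldin.

For a candidate number of clusters k the pipeline reports three criteria:

* **Inertia** — the K-means objective E; the "elbow" of its curve over k
  marks diminishing returns.  :func:`knee_point` automates the visual read
  as the k with maximum perpendicular distance to the chord joining the
  first and last points of the curve.
* **Silhouette** — per point i, with a(i) the mean distance to its own
  cluster's other members and b(i) the smallest mean distance to another
  cluster, s(i) = 1 - a/b if a < b, 0 if a = b, b/a - 1 if a > b.
  Higher mean silhouette is better; values lie in [-1, 1].  Two variants of
  b(i) are offered: the standard mean over the other cluster (divide by
  |C_k|) and an "as_printed" variant dividing by |C_k| - 1, kept for
  comparison because some formulations write the same |C|-1 denominator for
  both a and b; the two converge as cluster sizes grow.
* **Davies-Bouldin** — with S_i the within-cluster dispersion
  ((1/T_i) sum |X_j - A_i|^p)^(1/p) about centroid A_i and M_ij the
  Minkowski-p distance between centroids, DB is the mean over clusters of
  max_{j != i} (S_i + S_j) / M_ij.  Lower is better.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, minkowski

from .cluster import kmeans_restarts

__all__ = [
    "ValidityReport",
    "silhouette_values",
    "davies_bouldin",
    "knee_point",
    "k_scan",
]


@dataclass(frozen=True)
class ValidityReport:
    k_values: tuple
    inertia: tuple
    silhouette_mean: tuple
    davies_bouldin: tuple
    knee_k: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": list(self.k_values),
                "inertia": list(self.inertia),
                "silhouette": list(self.silhouette_mean),
                "davies_bouldin": list(self.davies_bouldin),
            }
        )

    def best_k_silhouette(self) -> int:
        return int(self.k_values[int(np.argmax(self.silhouette_mean))])

    def best_k_davies_bouldin(self) -> int:
        return int(self.k_values[int(np.argmin(self.davies_bouldin))])


def silhouette_values(
    X: np.ndarray, labels: np.ndarray, variant: str = "standard"
) -> tuple[np.ndarray, float]:
    """Per-point silhouette values and their mean.

    a(i) excludes the self-distance, so it divides by |C_i| - 1; a point in
    a singleton cluster gets s(i) = 0.  b(i) is the minimum over the other
    clusters of the mean distance to that cluster's members ("standard":
    divide by |C_k|; "as_printed": divide by |C_k| - 1, falling back to 1
    for a singleton other-cluster).
    """
    if variant not in ("standard", "as_printed"):
        raise ValueError(f"unknown variant: {variant!r}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette is undefined for a single cluster")
    D = cdist(X, X)
    n = X.shape[0]
    members = {c: np.flatnonzero(labels == c) for c in uniq}
    s = np.zeros(n)
    for i in range(n):
        own = members[labels[i]]
        if own.size == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (own.size - 1)  # excludes d(i,i) = 0
        b = np.inf
        for c in uniq:
            if c == labels[i]:
                continue
            other = members[c]
            denom = other.size if variant == "standard" else max(other.size - 1, 1)
            b = min(b, D[i, other].sum() / denom)
        if a < b:
            s[i] = 1.0 - a / b
        elif a > b:
            s[i] = b / a - 1.0
        else:
            s[i] = 0.0
    return s, float(s.mean())


def davies_bouldin(X: np.ndarray, labels: np.ndarray, p: float = 2) -> float:
    """Davies-Bouldin index (lower is better); p is the Minkowski order.

    Raises when two cluster centroids coincide (the pairwise similarity is
    undefined there).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("Davies-Bouldin is undefined for a single cluster")
    centroids = np.stack([X[labels == c].mean(axis=0) for c in uniq])
    # S_i: p-th root of the mean p-th power of member-to-centroid distances
    S = np.array([
        float(np.mean(
            np.linalg.norm(X[labels == c] - centroids[ci], ord=2 if p == 2 else p, axis=1) ** p
        ) ** (1.0 / p))
        for ci, c in enumerate(uniq)
    ])
    N = uniq.size
    db_terms = np.empty(N)
    for i in range(N):
        worst = -np.inf
        for j in range(N):
            if i == j:
                continue
            M = minkowski(centroids[i], centroids[j], p=p)
            if M == 0.0:
                raise ValueError("coincident centroids: Davies-Bouldin undefined")
            worst = max(worst, (S[i] + S[j]) / M)
        db_terms[i] = worst
    return float(db_terms.mean())


def knee_point(k_values: Sequence[int], inertia: Sequence[float]) -> int:
    """Elbow detection: the k with maximum perpendicular distance to the chord.

    The chord joins the first and last (k, inertia) points; a near-linear
    curve makes every distance close to zero, in which case the returned
    knee is unreliable.  Requires at least three points and a non-increasing
    inertia curve.
    """
    k_arr = np.asarray(k_values, dtype=float)
    e_arr = np.asarray(inertia, dtype=float)
    if k_arr.size < 3:
        raise ValueError("knee detection needs at least three points")
    if np.any(np.diff(e_arr) > 0):
        raise ValueError("inertia must be non-increasing in k")
    p0 = np.array([k_arr[0], e_arr[0]])
    p1 = np.array([k_arr[-1], e_arr[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    pts = np.column_stack([k_arr, e_arr]) - p0
    dist = np.abs(pts[:, 0] * chord[1] - pts[:, 1] * chord[0]) / norm
    interior = slice(1, -1)
    best = 1 + int(np.argmax(dist[interior]))
    return int(k_values[best])


def k_scan(
    X: np.ndarray,
    k_range: Sequence[int] = range(2, 11),
    n_init: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    silhouette_variant: str = "standard",
) -> ValidityReport:
    """Run restart-selected K-means for each k and collect validity metrics.

    Deterministic given *seed*: each k draws its restarts from its own child
    stream of the master seed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k_list = [int(k) for k in k_range]
    if not k_list or max(k_list) > X.shape[0]:
        raise ValueError("k_range must be non-empty with max(k) <= n")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(k_list))
    inertia, sil, db = [], [], []
    for k, child in zip(k_list, children):
        res = kmeans_restarts(X, k, n_init=n_init, seed=child)
        inertia.append(res.objective)
        _, sm = silhouette_values(X, res.labels, variant=silhouette_variant)
        sil.append(sm)
        db.append(davies_bouldin(X, res.labels))
    knee = knee_point(k_list, inertia) if len(k_list) >= 3 and not np.any(np.diff(inertia) > 0) else None
    return ValidityReport(
        k_values=tuple(k_list),
        inertia=tuple(inertia),
        silhouette_mean=tuple(sil),
        davies_bouldin=tuple(db),
        knee_k=knee,
    )
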