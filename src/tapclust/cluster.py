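"""Lloyd-style K-means with exact-convergence stopping and restart selection.

The algorithm alternates an expectation step (assign each point to the
nearest centroid under Euclidean distance, ties to the lowest cluster
index) and a maximization step (move each centroid to the mean of its
members), stopping when no centroid moves.  The objective is the sum of
squared errors

    E = sum_i sum_{j in cluster i} ||x_ij - u_i||^2

Because a single random initialization can land in a poor local minimum,
:func:`kmeans_restarts` runs many independent starts (1000 by default) and
keeps the solution with the smallest E.

Initialization is Forgy-style: k distinct data rows sampled without
replacement, which guarantees non-degenerate starts.  An empty cluster is
repaired by re-seeding it with the point currently farthest from its own
centroid.  Restart randomness comes from per-restart child streams of one
master seed, so the selected solution does not depend on execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClusteringResult", "sse", "kmeans_single", "kmeans_restarts"]


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray        # (n,) int cluster index in [0, k)
    centroids: np.ndarray     # (k, d)
    objective: float          # E, sum of squared errors
    n_iter: int
    restart_index: int = 0
    converged: bool = True
    objective_trace: tuple = ()   # E after each assignment+update iteration

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def sse(X: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> float:
    """Sum of squared Euclidean distances of points to their assigned centroids."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if labels.min(initial=0) < 0 or labels.max(initial=-1) >= centroids.shape[0]:
        raise ValueError("label out of range")
    diff = X - centroids[labels]
    return float(np.einsum("ij,ij->", diff, diff))


def _check_X(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    return X


def kmeans_single(
    X: np.ndarray, k: int, init: np.ndarray, max_iter: int = 300
) -> ClusteringResult:
    """One K-means run from explicit initial centroids.

    Stops when the centroid matrix is exactly unchanged between iterations
    (or at *max_iter*, a safety cap against floating-point cycling).  The
    per-iteration objective trace, E evaluated after each assignment +
    centroid update, is non-increasing.
    """
    X = _check_X(X)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, n={n}], got {k}")
    centroids = np.array(init, dtype=float, copy=True)
    if centroids.shape != (k, X.shape[1]):
        raise ValueError("init has wrong shape")

    trace = []
    labels = np.zeros(n, dtype=int)
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        # expectation: nearest centroid, ties to the lowest index (argmin)
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        # repair empty clusters with the point farthest from its centroid
        for c in range(k):
            while not np.any(labels == c):
                point_d2 = d2[np.arange(n), labels]
                # only steal from clusters that keep >=1 member
                sizes = np.bincount(labels, minlength=k)
                cand = np.where(sizes[labels] > 1, point_d2, -np.inf)
                far = int(np.argmax(cand))
                if not np.isfinite(cand[far]):
                    break  # cannot repair (k == n with duplicates); leave empty
                labels[far] = c
        # maximization: mean of members (empty clusters keep their centroid)
        new_centroids = centroids.copy()
        for c in range(k):
            members = labels == c
            if members.any():
                new_centroids[c] = X[members].mean(axis=0)
        trace.append(sse(X, labels, new_centroids))
        if np.array_equal(new_centroids, centroids):
            converged = True
            break
        centroids = new_centroids

    return ClusteringResult(
        labels=labels,
        centroids=centroids,
        objective=sse(X, labels, centroids),
        n_iter=n_iter,
        converged=converged,
        objective_trace=tuple(trace),
    )


def kmeans_restarts(
    X: np.ndarray,
    k: int,
    n_init: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    max_iter: int = 300,
) -> ClusteringResult:
    """Best-of-*n_init* K-means: run many random starts, keep the minimum-E result.

    Each restart initializes from k distinct data rows drawn without
    replacement from its own child stream of the master seed.  Objective
    ties keep the lowest restart index.  Fully reproducible from *seed*.
    """
    X = _check_X(X)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, n={n}], got {k}")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    best: ClusteringResult | None = None
    for i, child in enumerate(ss.spawn(n_init)):
        rng = np.random.default_rng(child)
        idx = rng.choice(n, size=k, replace=False)
        res = kmeans_single(X, k, X[idx], max_iter=max_iter)
        if best is None or res.objective < best.objective:
            best = ClusteringResult(
                labels=res.labels, centroids=res.centroids, objective=res.objective,
                n_iter=res.n_iter, restart_index=i, converged=res.converged,
                objective_trace=res.objective_trace,
            )
    assert best is not None
    return best
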