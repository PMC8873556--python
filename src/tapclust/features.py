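"""Tapping features: inter-tap intervals, positional drift, and the nine-feature vector.

Three base series are derived from a session.  ``TapInter`` is the sequence
of differences between consecutive tap timestamps.  The tap positions are
split into a left and a right set by the mean x-coordinate (left: x < mean,
right: x >= mean), matching the two-target geometry of the task;
``DriftLeft`` / ``DriftRight`` are the Euclidean distances between
consecutive tap positions within each side.

Nine features summarize a session: corXY, numberTaps, skewDriftRight,
skewDriftLeft, cvTapInter, cvDriftRight, cvDriftLeft, meanTapInter,
medianTapInter.  Skewness is the third standardized moment with the
population (divide-by-N) scale s = sqrt(sum((x-mu)^2)/N); the coefficient
of variation is sigma/mu * 100 with the same population sigma.  A ``ddof``
switch exposes the sample (N-1) variants for sensitivity checks.

Degenerate inputs (too-short series, zero dispersion, zero mean, constant
coordinate) yield NaN, which marks the feature missing; missing rows are
dropped, with a log, when the cohort matrix is assembled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .ingest import TapSession

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "tap_intervals",
    "split_sides",
    "consecutive_drifts",
    "skewness",
    "coeff_variation",
    "pearson_xy",
    "extract_features",
    "extract_cohort",
    "assemble_matrix",
    "minmax_normalize",
]

#: fixed column order of the cohort feature matrix
FEATURE_NAMES = (
    "corXY",
    "numberTaps",
    "skewDriftRight",
    "skewDriftLeft",
    "cvTapInter",
    "cvDriftRight",
    "cvDriftLeft",
    "meanTapInter",
    "medianTapInter",
)


@dataclass(frozen=True)
class FeatureVector:
    """The nine tapping features for one session; NaN flags a missing value."""

    corXY: float
    numberTaps: float
    skewDriftRight: float
    skewDriftLeft: float
    cvTapInter: float
    cvDriftRight: float
    cvDriftLeft: float
    meanTapInter: float
    medianTapInter: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def missing(self) -> tuple[str, ...]:
        return tuple(n for n in FEATURE_NAMES if math.isnan(getattr(self, n)))

    @property
    def complete(self) -> bool:
        return not self.missing()


def tap_intervals(s: TapSession) -> np.ndarray:
    """Differences between consecutive tap timestamps, length n-1 (empty for n<2)."""
    return np.diff(s.t)


def split_sides(s: TapSession) -> tuple[np.ndarray, np.ndarray]:
    """Split tap positions at the mean x: left is x < mean, right is x >= mean.

    Returns two (m, 2) arrays of (x, y) rows in original time order.  With
    all x equal the left side is empty and the right side holds every tap.
    """
    if s.n_taps == 0:
        raise ValueError("cannot split an empty session")
    pts = np.column_stack([s.x, s.y])
    left_mask = s.x < float(np.mean(s.x))
    return pts[left_mask], pts[~left_mask]


def consecutive_drifts(points: np.ndarray) -> np.ndarray:
    """Euclidean distances between consecutive positions; empty for <2 points."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.shape[0] < 2:
        return np.empty(0)
    return np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))


def skewness(xs, ddof: int = 0) -> float:
    """Third standardized moment, population scale by default.

    skew = (sum((x-mu)^3)/N) / s^3 with s = sqrt(sum((x-mu)^2)/(N-ddof)).
    Returns NaN for fewer than two values or zero dispersion.
    """
    x = np.asarray(xs, dtype=float)
    n = x.size
    if n < 2:
        return float("nan")
    mu = x.mean()
    s = math.sqrt(float(np.sum((x - mu) ** 2)) / (n - ddof))
    if s == 0.0:
        return float("nan")
    m3 = float(np.sum((x - mu) ** 3)) / n
    return m3 / s**3


def coeff_variation(xs, ddof: int = 0) -> float:
    """Coefficient of variation in percent: sigma/mu * 100 (population sigma).

    Returns NaN for fewer than two values or zero mean.
    """
    x = np.asarray(xs, dtype=float)
    if x.size < 2:
        return float("nan")
    mu = x.mean()
    if mu == 0.0:
        return float("nan")
    sigma = x.std(ddof=ddof)
    return float(sigma / mu * 100.0)


def pearson_xy(s: TapSession) -> float:
    """Pearson correlation between tap x and y coordinates; NaN when either is constant."""
    if s.n_taps < 2 or np.ptp(s.x) == 0 or np.ptp(s.y) == 0:
        return float("nan")
    return float(np.corrcoef(s.x, s.y)[0, 1])


def extract_features(s: TapSession, ddof: int = 0) -> FeatureVector:
    """Compute the nine tapping features for one session.

    The even-length median is the mean of the two central order statistics.
    Any degenerate component propagates as NaN.
    """
    inter = tap_intervals(s)
    left, right = split_sides(s)
    dl = consecutive_drifts(left)
    dr = consecutive_drifts(right)
    if inter.size:
        mean_ti, median_ti = float(inter.mean()), float(np.median(inter))
    else:
        mean_ti = median_ti = float("nan")
    return FeatureVector(
        corXY=pearson_xy(s),
        numberTaps=float(s.n_taps),
        skewDriftRight=skewness(dr, ddof=ddof),
        skewDriftLeft=skewness(dl, ddof=ddof),
        cvTapInter=coeff_variation(inter, ddof=ddof),
        cvDriftRight=coeff_variation(dr, ddof=ddof),
        cvDriftLeft=coeff_variation(dl, ddof=ddof),
        meanTapInter=mean_ti,
        medianTapInter=median_ti,
    )


def extract_cohort(sessions: Sequence[TapSession], ddof: int = 0) -> tuple[list[FeatureVector], list[str]]:
    """Feature vectors plus row identifiers (participant_id@recorded_at) for a cohort."""
    vectors = [extract_features(s, ddof=ddof) for s in sessions]
    ids = [f"{s.participant_id}@{s.recorded_at:g}" for s in sessions]
    return vectors, ids


def assemble_matrix(
    vectors: Sequence[FeatureVector],
    row_ids: Optional[Sequence[str]] = None,
    policy: str = "drop",
) -> tuple[pd.DataFrame, list[tuple[str, tuple[str, ...]]]]:
    """Assemble the cohort feature matrix, dropping rows with missing features.

    Returns the matrix (rows indexed by id, columns in ``FEATURE_NAMES``
    order) and a log of dropped rows with the names of the missing features.
    Raises if no complete row remains.
    """
    if policy != "drop":
        raise ValueError(f"unknown missing-value policy: {policy!r}")
    if row_ids is None:
        row_ids = [str(i) for i in range(len(vectors))]
    if len(row_ids) != len(vectors):
        raise ValueError("row_ids and vectors length mismatch")
    rows, kept_ids, dropped = [], [], []
    for rid, v in zip(row_ids, vectors):
        miss = v.missing()
        if miss:
            dropped.append((rid, miss))
        else:
            rows.append(v.as_array())
            kept_ids.append(rid)
    if not rows:
        raise ValueError("empty cohort: every session had at least one missing feature")
    df = pd.DataFrame(rows, index=pd.Index(kept_ids, name="id"), columns=list(FEATURE_NAMES))
    return df, dropped


def minmax_normalize(m: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Min-max scale every column to [0, 1]: x' = (x - min) / (max - min).

    A constant column maps to all zeros.  Returns the scaled matrix and the
    per-column (min, max) scaler so the transform is invertible/reusable.
    """
    if m.shape[0] < 2:
        raise ValueError("need at least two rows to normalize")
    scaler: dict[str, tuple[float, float]] = {}
    out = m.copy()
    for col in m.columns:
        lo, hi = float(m[col].min()), float(m[col].max())
        scaler[col] = (lo, hi)
        out[col] = 0.0 if hi == lo else (m[col] - lo) / (hi - lo)
    return out, scaler
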