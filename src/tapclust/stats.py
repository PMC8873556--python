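"""Cluster characterization, questionnaire summaries, severity bands, and PCA.

Characterization asks, per (cluster, feature): is the cluster's mean of
that tapping feature different from the whole cohort's mean (the baseline)?
Each cell is a two-sided one-sample t-test of the cluster members against
the cohort mean, Bonferroni-corrected over the full table (all clusters x
all features, the most conservative natural family), holding the
family-wise error at 0.05.  A significant cell is reported as a direction
(+/-) with 1, 2 or 3 markers for adjusted p below 0.05, 0.01 and 0.001.

Questionnaire summaries report mean +/- SEM (sample sd / sqrt(n)) per
cluster for the Part-I, Part-II, total and PDQ-8 scores; PDQ-8 is averaged
over the subset of participants who completed it.

Because the mobile survey administers only a subset of the Part-I/II items,
subscale scores are re-scaled linearly onto the full instruments before
severity banding (mild / moderate / severe by two configurable cut-offs);
cut-offs and full-scale maxima are configuration with documented defaults,
not measured quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES
from .ingest import SurveyRecord

__all__ = [
    "TTestResult",
    "SeverityBands",
    "PCAProjection",
    "one_sample_t",
    "characterize",
    "direction_symbol",
    "summarize_scores",
    "rescale_subscale",
    "assign_band",
    "band_percentages",
    "pca_project",
    "DEFAULT_BANDS",
]

BAND_NAMES = ("mild", "moderate", "severe")


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    df: int
    p_raw: float
    p_adjusted: Optional[float] = None

    @property
    def defined(self) -> bool:
        return math.isfinite(self.t_stat)


def one_sample_t(xs, mu0: float) -> TTestResult:
    """Two-sided one-sample t-test of mean(xs) against mu0.

    t = (mean - mu0) / (sd / sqrt(n)) with the sample (N-1) standard
    deviation; p from the t distribution with n-1 degrees of freedom.
    Zero dispersion or n < 2 yields an undefined result (NaN statistic),
    reported downstream as "no direction".
    """
    x = np.asarray(xs, dtype=float)
    n = x.size
    if n < 2:
        return TTestResult(float("nan"), max(n - 1, 0), float("nan"))
    sd = x.std(ddof=1)
    if sd == 0.0:
        return TTestResult(float("nan"), n - 1, float("nan"))
    t = (x.mean() - mu0) / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TTestResult(float(t), n - 1, float(p))


def _markers(p_adj: float) -> int:
    if not math.isfinite(p_adj):
        return 0
    return sum(p_adj < thr for thr in (0.05, 0.01, 0.001))


def characterize(
    features_unscaled: pd.DataFrame,
    labels: np.ndarray,
    fwe: float = 0.05,
    marker_basis: str = "adjusted",
) -> pd.DataFrame:
    """Direction table: each cluster's features tested against the cohort mean.

    Returns one row per (cluster, feature) with t, df, raw and
    Bonferroni-adjusted p (family = all clusters x all features),
    ``direction`` in {"plus", "minus", "none"} and ``markers`` in 0..3.
    *marker_basis* selects whether the significance markers are read off
    the adjusted (default) or raw p-values.
    """
    if marker_basis not in ("adjusted", "raw"):
        raise ValueError(f"unknown marker_basis: {marker_basis!r}")
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("characterization needs at least two clusters")
    cols = [c for c in features_unscaled.columns]
    m = clusters.size * len(cols)  # Bonferroni family size
    rows = []
    for c in clusters:
        member_mask = labels == c
        for feat in cols:
            values = features_unscaled.loc[member_mask, feat].to_numpy()
            mu0 = float(features_unscaled[feat].mean())
            res = one_sample_t(values, mu0)
            p_adj = min(1.0, m * res.p_raw) if math.isfinite(res.p_raw) else float("nan")
            basis_p = p_adj if marker_basis == "adjusted" else res.p_raw
            markers = _markers(basis_p)
            significant = math.isfinite(p_adj) and p_adj < fwe
            if significant and markers:
                direction = "plus" if values.mean() > mu0 else "minus"
            else:
                direction, markers = "none", 0
            rows.append(
                {
                    "cluster": int(c),
                    "feature": feat,
                    "t": res.t_stat,
                    "df": res.df,
                    "p_raw": res.p_raw,
                    "p_adjusted": p_adj,
                    "direction": direction,
                    "markers": markers,
                    "family_size": m,
                }
            )
    return pd.DataFrame(rows)


def direction_symbol(direction: str, markers: int) -> str:
    """Render a characterization cell the way the direction tables print it."""
    if direction == "none" or markers == 0:
        return "N.S."
    ch = "+" if direction == "plus" else "-"
    return ch * markers


def summarize_scores(paired_surveys: Sequence[SurveyRecord], labels: np.ndarray) -> pd.DataFrame:
    """Mean +/- SEM of questionnaire scores per cluster.

    Scales: updrs1, updrs2, total (= updrs1 + updrs2), pdq8.  PDQ-8 rows
    count only participants who completed it.  SEM uses the sample sd; a
    cluster with fewer than two values gets NaN SEM.
    """
    labels = np.asarray(labels)
    if len(paired_surveys) != labels.size:
        raise ValueError("labels and surveys length mismatch")
    rows = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        for scale in ("updrs1", "updrs2", "total", "pdq8"):
            vals = []
            for i in idx:
                sv = paired_surveys[i]
                v = getattr(sv, scale)
                if v is not None:
                    vals.append(float(v))
            arr = np.asarray(vals)
            n = arr.size
            mean = float(arr.mean()) if n else float("nan")
            sem = float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else float("nan")
            rows.append({"cluster": int(c), "scale": scale, "mean": mean, "sem": sem, "n": n})
    return pd.DataFrame(rows)


def rescale_subscale(raw: float, max_subset: int, max_full: int) -> float:
    """Map an item-subset score onto the full instrument by linear proportion."""
    if not 0 <= raw <= max_subset:
        raise ValueError(f"raw score {raw} outside 0..{max_subset}")
    return raw * max_full / max_subset


@dataclass(frozen=True)
class SeverityBands:
    """Severity banding for one subscale on the full-instrument score range.

    mild: score <= cut_mild_moderate; moderate: up to and including
    cut_moderate_severe; severe: above.  Cut-offs follow the published
    percentile/ROC/ordinal-regression triangulation approach for the
    MDS-UPDRS subscales and are configuration, with these defaults:
    Part I full max 52 with cuts (10, 21); Part II full max 52 with cuts
    (12, 29).
    """

    max_subset: int
    max_full: int
    cut_mild_moderate: float
    cut_moderate_severe: float

    def __post_init__(self):
        if not self.cut_mild_moderate < self.cut_moderate_severe:
            raise ValueError("cut-offs must be strictly increasing")
        if self.max_subset <= 0 or self.max_full <= 0:
            raise ValueError("scale maxima must be positive")


DEFAULT_BANDS = {
    "updrs1": SeverityBands(max_subset=24, max_full=52, cut_mild_moderate=10, cut_moderate_severe=21),
    "updrs2": SeverityBands(max_subset=40, max_full=52, cut_mild_moderate=12, cut_moderate_severe=29),
}


def assign_band(score_full_scale: float, bands: SeverityBands) -> str:
    """Band a full-scale score: boundaries belong to the lower band."""
    if score_full_scale <= bands.cut_mild_moderate:
        return "mild"
    if score_full_scale <= bands.cut_moderate_severe:
        return "moderate"
    return "severe"


def band_percentages(bands_assigned: Sequence[str], labels: np.ndarray) -> pd.DataFrame:
    """Per-cluster percentage of participants in each severity band (rows sum to 100)."""
    labels = np.asarray(labels)
    if len(bands_assigned) != labels.size:
        raise ValueError("labels and band assignments length mismatch")
    bands_arr = np.asarray(bands_assigned)
    rows = []
    for c in np.unique(labels):
        sub = bands_arr[labels == c]
        if sub.size == 0:
            raise ValueError(f"empty cluster {c}: percentages undefined")
        row = {"cluster": int(c)}
        for b in BAND_NAMES:
            row[b] = 100.0 * float(np.sum(sub == b)) / sub.size
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PCAProjection:
    coordinates: np.ndarray          # (n, d) component scores, zero-mean columns
    explained_variance_pct: np.ndarray  # (d,) non-increasing, each in [0, 100]
    loadings: np.ndarray             # (d, p) right singular vectors (sign-fixed)


def pca_project(X, d: int = 2) -> PCAProjection:
    """Project rows of X onto the top-d principal components.

    Columns are centered; components come from the SVD of the centered
    matrix.  Explained percentage is each component's variance share of the
    total.  The sign of every component is fixed so that its
    largest-magnitude loading is positive, making plots reproducible.  If
    the matrix rank is below d, fewer components are returned with a
    warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n <= d:
        raise ValueError("need more rows than components")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(Xc.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    d_eff = min(d, rank)
    if d_eff < d:
        import warnings

        warnings.warn(f"matrix rank {rank} < requested {d} components; returning {d_eff}")
    scores = U[:, :d_eff] * s[:d_eff]
    load = Vt[:d_eff]
    for j in range(d_eff):
        i_max = int(np.argmax(np.abs(load[j])))
        if load[j, i_max] < 0:
            load[j] = -load[j]
            scores[:, j] = -scores[:, j]
    total_var = float(np.sum(s**2))
    explained = (s[:d_eff] ** 2) / total_var * 100.0
    return PCAProjection(coordinates=scores, explained_variance_pct=explained, loadings=load)
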