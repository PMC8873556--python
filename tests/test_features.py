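"""The nine tapping features, the cohort matrix, and min-max scaling."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tapclust import (
    FEATURE_NAMES,
    assemble_matrix,
    coeff_variation,
    consecutive_drifts,
    extract_features,
    minmax_normalize,
    parse_tap_sessions,
    pearson_xy,
    skewness,
    split_sides,
    tap_intervals,
)

from conftest import make_session, random_session


def pure_python_skew(v):
    """Independent direct-formula evaluation (population moments)."""
    n = len(v)
    mu = statistics.fmean(v)
    s = math.sqrt(math.fsum((u - mu) ** 2 for u in v) / n)
    return (math.fsum((u - mu) ** 3 for u in v) / n) / s**3


def pure_python_cv(v):
    mu = statistics.fmean(v)
    sigma = math.sqrt(math.fsum((u - mu) ** 2 for u in v) / len(v))
    return sigma / mu * 100


class TestSeries:
    @pytest.mark.parametrize(
        "t, expected",
        [
            ([0.0, 0.5, 1.5], [0.5, 1.0]),
            ([0.0], []),
            ([0.0, 0.3, 0.9, 1.0], [0.3, 0.6, 0.1]),
        ],
    )
    def test_tap_intervals(self, t, expected):
        s = make_session(t, np.zeros(len(t)), np.zeros(len(t)))
        assert tap_intervals(s) == pytest.approx(expected)

    def test_split_strict_below_mean_goes_left(self):
        s = make_session([0, 1, 2, 3], [0, 10, 0, 10], [5, 6, 7, 8])
        left, right = split_sides(s)
        assert left[:, 0].tolist() == [0.0, 0.0] and left[:, 1].tolist() == [5.0, 7.0]
        assert right[:, 0].tolist() == [10.0, 10.0]

    def test_split_constant_x_all_right(self):
        s = make_session([0, 1], [4, 4], [0, 1])
        left, right = split_sides(s)
        assert left.shape[0] == 0 and right.shape[0] == 2

    def test_split_boundary_at_mean(self):
        s = make_session([0, 1, 2], [0, 4, 10], [0, 0, 0])  # mean x = 4.667
        left, right = split_sides(s)
        assert left[:, 0].tolist() == [0.0, 4.0]
        assert right[:, 0].tolist() == [10.0]

    @pytest.mark.parametrize(
        "pts, expected",
        [
            ([(0, 0), (3, 4)], [5.0]),
            ([(0, 0)], []),
            ([(0, 0), (0, 0), (1, 0)], [0.0, 1.0]),
        ],
    )
    def test_consecutive_drifts(self, pts, expected):
        assert consecutive_drifts(np.array(pts, dtype=float).reshape(-1, 2)) == pytest.approx(expected)


class TestScalarStatistics:
    def test_skewness_symmetric_is_zero(self):
        assert skewness([1, 2, 3]) == pytest.approx(0.0)

    def test_skewness_hand_value(self):
        # mu=2, third moment 2, population s = sqrt(2) -> 2 / (2*sqrt(2))
        assert skewness([1, 1, 4]) == pytest.approx(0.70711, abs=1e-5)

    def test_skewness_degenerate(self):
        assert math.isnan(skewness([5, 5, 5]))
        assert math.isnan(skewness([5]))

    def test_cv_values(self):
        assert coeff_variation([2, 2, 2]) == pytest.approx(0.0)
        assert coeff_variation([1, 3]) == pytest.approx(50.0)
        assert math.isnan(coeff_variation([0, 0]))

    def test_sample_ddof_variant_differs(self):
        assert coeff_variation([1, 3], ddof=1) == pytest.approx(math.sqrt(2) / 2 * 100)
        assert abs(skewness([1, 1, 4], ddof=1)) < abs(skewness([1, 1, 4]) + 1)  # defined

    @given(st.lists(st.floats(-100, 100), min_size=3, max_size=40))
    def test_agrees_with_direct_formula_oracle(self, xs):
        x = [round(v, 6) for v in xs]
        mu = statistics.fmean(x)
        s = math.sqrt(math.fsum((u - mu) ** 2 for u in x) / len(x))
        if s < 1e-9 or abs(mu) < 1e-9:
            return
        assert skewness(x) == pytest.approx(pure_python_skew(x), rel=1e-12, abs=1e-12)
        assert coeff_variation(x) == pytest.approx(pure_python_cv(x), rel=1e-12, abs=1e-12)

    def test_pearson_xy(self):
        assert pearson_xy(make_session([0, 1, 2], [0, 1, 2], [0, 1, 2])) == pytest.approx(1.0)
        assert pearson_xy(make_session([0, 1], [0, 1], [1, 0])) == pytest.approx(-1.0)
        assert math.isnan(pearson_xy(make_session([0, 1, 2], [0, 1, 2], [0, 0, 0])))


class TestExtract:
    def test_four_alternating_taps(self):
        s = make_session([0, 0.5, 1.0, 1.5], [0, 10, 0, 10], [0, 0, 0, 0])
        v = extract_features(s)
        assert v.numberTaps == 4
        assert v.meanTapInter == pytest.approx(0.5)
        assert v.medianTapInter == pytest.approx(0.5)
        assert v.cvTapInter == pytest.approx(0.0)
        # each side has a single drift gap: skew and cv are missing
        assert math.isnan(v.skewDriftLeft) and math.isnan(v.cvDriftLeft)
        assert math.isnan(v.skewDriftRight) and math.isnan(v.cvDriftRight)

    def test_worked_session_matches_frozen_expectation(
        self, worked_session_path, worked_session_expected
    ):
        (s,) = parse_tap_sessions(worked_session_path)
        v = extract_features(s)
        for name, expected in worked_session_expected.items():
            assert getattr(v, name) == pytest.approx(expected, rel=1e-10), name

    def test_time_shift_invariance(self, random_session_factory):
        s = random_session_factory(seed=1)
        v1, v2 = extract_features(s), extract_features(s.shifted(dt=7.0))
        assert np.allclose(v1.as_array(), v2.as_array(), equal_nan=True)

    @given(st.integers(0, 2**31 - 1))
    def test_translation_invariance(self, seed):
        s = random_session(seed=seed)
        v1 = extract_features(s)
        v2 = extract_features(s.shifted(dx=37.5, dy=-12.25))
        assert np.allclose(v1.as_array(), v2.as_array(), equal_nan=True, rtol=1e-9, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_isotropic_scaling_leaves_dimensionless_features(self, seed):
        s = random_session(seed=seed)
        scaled = make_session(s.t, 3.0 * s.x, 3.0 * s.y)
        v1, v2 = extract_features(s), extract_features(scaled)
        for name in ("corXY", "skewDriftRight", "skewDriftLeft", "cvDriftRight", "cvDriftLeft"):
            assert getattr(v1, name) == pytest.approx(getattr(v2, name), rel=1e-9), name


class TestMatrix:
    def _vec(self, **overrides):
        base = {n: 1.0 for n in FEATURE_NAMES}
        base.update(overrides)
        from tapclust import FeatureVector

        return FeatureVector(**base)

    def test_complete_vectors_assemble(self):
        m, dropped = assemble_matrix([self._vec(corXY=0.1), self._vec(corXY=0.2), self._vec()])
        assert m.shape == (3, 9) and dropped == []
        assert list(m.columns) == list(FEATURE_NAMES)

    def test_missing_feature_row_dropped_and_logged(self):
        m, dropped = assemble_matrix([self._vec(), self._vec(skewDriftLeft=float("nan"))])
        assert m.shape == (1, 9)
        assert dropped == [("1", ("skewDriftLeft",))]

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError, match="empty cohort"):
            assemble_matrix([self._vec(corXY=float("nan"))])

    def test_minmax_examples(self):
        df = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [5.0, 5.0, 5.0], "c": [0.0, 1.0, 0.25]})
        scaled, scaler = minmax_normalize(df)
        assert scaled["a"].tolist() == [0.0, 0.5, 1.0]
        assert scaled["b"].tolist() == [0.0, 0.0, 0.0]  # constant column convention
        assert scaled["c"].tolist() == [0.0, 1.0, 0.25]  # already spanning [0,1]
        assert scaler["a"] == (2.0, 6.0)

    @given(st.integers(0, 10_000))
    def test_minmax_contract(self, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("abcd"))
        scaled, _ = minmax_normalize(df)
        assert ((scaled >= 0) & (scaled <= 1)).all().all()
        for col in scaled:
            assert scaled[col].min() == 0.0 and scaled[col].max() == 1.0
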