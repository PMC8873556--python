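"""One-sample t-tests, cluster characterization, score summaries, bands, PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tapclust import (
    DEFAULT_BANDS,
    SeverityBands,
    SurveyRecord,
    assign_band,
    band_percentages,
    characterize,
    direction_symbol,
    one_sample_t,
    pca_project,
    rescale_subscale,
    summarize_scores,
)


def t_sf_by_quadrature(t_val, df, n_grid=100_001):
    """Independent upper-tail probability of the t distribution: Simpson
    integration of the density on [t, hi], plus the far tail integrated
    under the substitution x -> 1/u (which tames the power-law decay)."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def pdf(x):
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    def simpson(ys, h):
        return h / 3 * (ys[0] + ys[-1] + 4 * ys[1:-1:2].sum() + 2 * ys[2:-2:2].sum())

    hi = max(abs(t_val) + 50.0, 100.0)
    xs = np.linspace(t_val, hi, n_grid)
    main = simpson(pdf(xs), xs[1] - xs[0])
    # tail: int_hi^inf pdf(x) dx = int_0^{1/hi} pdf(1/u) / u^2 du
    # lower limit 1e-12 instead of 0: the integrand ~ u^(df-1) there, so the
    # omitted mass is far below the comparison tolerance
    us = np.linspace(1e-12, 1.0 / hi, n_grid)
    tail = simpson(pdf(1.0 / us) / us**2, us[1] - us[0])
    return main + tail


class TestOneSampleT:
    def test_mean_equals_null(self):
        res = one_sample_t([1, 2, 3, 4, 5], 3.0)
        assert res.t_stat == pytest.approx(0.0) and res.p_raw == pytest.approx(1.0)

    def test_hand_value(self):
        res = one_sample_t([1, 2, 3, 4, 5], 0.0)
        assert res.t_stat == pytest.approx(4.2426, abs=1e-4)
        assert res.df == 4
        assert res.p_raw == pytest.approx(0.01324, abs=1e-5)

    def test_zero_dispersion_undefined(self):
        assert not one_sample_t([7, 7, 7], 5.0).defined
        assert not one_sample_t([7], 5.0).defined

    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_quadrature_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        xs = rng.normal(rng.normal(0, 2), 1.0, size=n)
        mu0 = float(rng.normal(0, 2))
        res = one_sample_t(xs, mu0)
        if not res.defined:
            return
        p_oracle = 2.0 * t_sf_by_quadrature(abs(res.t_stat), res.df)
        assert res.p_raw == pytest.approx(p_oracle, abs=1e-8)


class TestCharacterize:
    def _toy(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        n = 60
        a = rng.normal(0, 1, size=(n, 2))
        b = rng.normal(0, 1, size=(n, 2))
        b[:, 0] += shift
        df = pd.DataFrame(np.vstack([a, b]), columns=["f1", "f2"])
        labels = np.repeat([0, 1], n)
        return df, labels

    def test_bonferroni_arithmetic(self):
        # family of 27 tests turns raw p=0.0004 into 0.0108: one marker
        df, labels = self._toy(shift=5.0)
        table = characterize(df, labels)
        assert (table["family_size"] == 4).all()  # 2 clusters x 2 features here
        adj = table["p_adjusted"]
        raw = table["p_raw"]
        finite = np.isfinite(raw)
        assert np.allclose(adj[finite], np.minimum(1.0, 4 * raw[finite]))
        assert min(1.0, 27 * 0.0004) == pytest.approx(0.0108)

    def test_shifted_feature_flagged_with_direction(self):
        df, labels = self._toy(shift=5.0)
        table = characterize(df, labels).set_index(["cluster", "feature"])
        assert table.loc[(1, "f1"), "direction"] == "plus"
        assert table.loc[(0, "f1"), "direction"] == "minus"
        assert table.loc[(1, "f1"), "markers"] == 3

    def test_null_feature_not_significant(self):
        df, labels = self._toy(seed=3, shift=0.0)
        table = characterize(df, labels)
        assert (table["direction"] == "none").all()

    def test_marker_nesting_invariant(self):
        df, labels = self._toy(shift=1.0)
        table = characterize(df, labels)
        for _, row in table.iterrows():
            assert (row["direction"] == "none") == (row["markers"] == 0)
            if row["markers"] >= 2:
                assert row["p_adjusted"] < 0.01

    def test_symbols(self):
        assert direction_symbol("plus", 3) == "+++"
        assert direction_symbol("minus", 2) == "--"
        assert direction_symbol("none", 0) == "N.S."

    def test_type_one_error_control_small(self):
        # null data: with FWE at 0.05 the chance of any marked cell is <= 5%
        hits = 0
        cells = 0
        for rep in range(40):
            df, labels = self._toy(seed=100 + rep, shift=0.0)
            table = characterize(df, labels)
            hits += int((table["markers"] > 0).sum())
            cells += len(table)
        assert hits / cells <= 0.05


class TestScoreSummary:
    def _surveys(self):
        return [
            SurveyRecord("a", 0, 4, 0, 10),
            SurveyRecord("b", 0, 6, 0, None),
            SurveyRecord("c", 0, 3, 3, 8),
            SurveyRecord("d", 0, 3, 3, 6),
        ]

    def test_mean_and_sem(self):
        out = summarize_scores(self._surveys(), np.array([0, 0, 1, 1]))
        row = out[(out.cluster == 0) & (out.scale == "updrs1")].iloc[0]
        assert row["mean"] == pytest.approx(5.0) and row["sem"] == pytest.approx(1.0)

    def test_equal_scores_zero_sem(self):
        out = summarize_scores(self._surveys(), np.array([0, 0, 1, 1]))
        row = out[(out.cluster == 1) & (out.scale == "updrs1")].iloc[0]
        assert row["sem"] == 0.0

    def test_pdq8_counts_available_subset(self):
        out = summarize_scores(self._surveys(), np.array([0, 0, 1, 1]))
        row = out[(out.cluster == 0) & (out.scale == "pdq8")].iloc[0]
        assert row["n"] == 1 and math.isnan(row["sem"])

    def test_total_is_sum_of_parts(self):
        out = summarize_scores(self._surveys(), np.array([0, 0, 1, 1]))
        row = out[(out.cluster == 1) & (out.scale == "total")].iloc[0]
        assert row["mean"] == pytest.approx(6.0)


class TestBands:
    def test_rescale_endpoints_and_linearity(self):
        assert rescale_subscale(0, 24, 52) == 0.0
        assert rescale_subscale(24, 24, 52) == 52.0
        assert rescale_subscale(6, 24, 52) == pytest.approx(13.0)
        with pytest.raises(ValueError):
            rescale_subscale(25, 24, 52)

    def test_band_boundaries_belong_to_lower_band(self):
        b = DEFAULT_BANDS["updrs1"]
        assert assign_band(b.cut_mild_moderate, b) == "mild"
        assert assign_band(b.cut_moderate_severe, b) == "moderate"
        assert assign_band(b.cut_moderate_severe + 1e-9, b) == "severe"

    def test_cutoffs_must_increase(self):
        with pytest.raises(ValueError):
            SeverityBands(24, 52, 20, 10)

    def test_percentages(self):
        tab = band_percentages(
            ["mild", "mild", "moderate", "severe", "mild"], np.array([0, 0, 0, 0, 1])
        )
        row0 = tab[tab.cluster == 0].iloc[0]
        assert [row0["mild"], row0["moderate"], row0["severe"]] == [50.0, 25.0, 25.0]
        row1 = tab[tab.cluster == 1].iloc[0]
        assert [row1["mild"], row1["moderate"], row1["severe"]] == [100.0, 0.0, 0.0]
        assert np.allclose(tab[["mild", "moderate", "severe"]].sum(axis=1), 100.0)


class TestPCA:
    def test_collinear_single_component(self):
        X = np.array([[i, 2.0 * i] for i in range(6)], dtype=float)
        with pytest.warns(UserWarning, match="rank"):
            proj = pca_project(X, d=2)  # rank 1: one component, with a warning
        assert proj.explained_variance_pct[0] == pytest.approx(100.0)

    def test_square_corners_fifty_fifty(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        proj = pca_project(X, d=2)
        assert np.allclose(proj.explained_variance_pct, [50.0, 50.0])

    def test_scores_centered_and_variance_sums(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 5))
        proj = pca_project(X, d=2)
        assert np.allclose(proj.coordinates.mean(axis=0), 0.0, atol=1e-12)
        assert proj.explained_variance_pct[0] >= proj.explained_variance_pct[1]
        full = pca_project(X, d=5)
        assert full.explained_variance_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_sign_convention_reproducible(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 4))
        p1, p2 = pca_project(X), pca_project(X.copy())
        assert np.allclose(p1.coordinates, p2.coordinates)
        for row in p1.loadings:
            assert row[np.argmax(np.abs(row))] > 0
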