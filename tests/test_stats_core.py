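"""From-formula statistics versus independent oracles (scipy, statsmodels,
brute-force recomputation) and their structural invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.special import kolmogorov

from glyscreen import (
    DegenerateTableError,
    Table2x2,
    ValidationError,
    bonferroni,
    chi2_2x2,
    fit_logistic,
    ks_two_sample,
    predict_probability,
)


class TestChi2:
    @pytest.mark.parametrize(
        "cells, stat, p",
        [
            # BPH-without-drug diabetics vs non-BPH diabetics (253 vs 246 patients)
            ((151, 102, 119, 127), 6.4249, 0.011253),
            # matched alpha-blocker comparison reconstructed from group sizes
            # 1356/1221 at 61%/53% success
            ((827, 529, 647, 574), 16.7908, 4.17e-5),
            ((10, 10, 10, 10), 0.0, 1.0),
        ],
    )
    def test_reference_tables(self, cells, stat, p):
        res = chi2_2x2(Table2x2(*cells))
        assert res.statistic == pytest.approx(stat, abs=5e-4)
        assert res.p_value == pytest.approx(p, rel=5e-3)
        assert res.df == 1

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            cells = rng.integers(1, 400, 4)
            res = chi2_2x2(Table2x2(*cells))
            ref = sps.chi2_contingency(cells.reshape(2, 2), correction=False)
            assert abs(res.statistic - ref.statistic) < 1e-10
            assert abs(res.p_value - ref.pvalue) < 1e-10
            resy = chi2_2x2(Table2x2(*cells), continuity_correction=True)
            refy = sps.chi2_contingency(cells.reshape(2, 2), correction=True)
            assert abs(resy.statistic - refy.statistic) < 1e-10

    def test_invariant_under_row_and_column_swaps(self):
        t = Table2x2(30, 70, 50, 50)
        swapped_rows = Table2x2(50, 50, 30, 70)
        swapped_cols = Table2x2(70, 30, 50, 50)
        s = chi2_2x2(t).statistic
        assert chi2_2x2(swapped_rows).statistic == pytest.approx(s, abs=1e-12)
        assert chi2_2x2(swapped_cols).statistic == pytest.approx(s, abs=1e-12)

    def test_statistic_scales_linearly_in_counts(self):
        t = Table2x2(30, 70, 50, 50)
        t3 = Table2x2(90, 210, 150, 150)
        assert chi2_2x2(t3).statistic == pytest.approx(3 * chi2_2x2(t).statistic)

    def test_zero_margin_is_degenerate(self):
        with pytest.raises(DegenerateTableError, match="degenerate"):
            chi2_2x2(Table2x2(0, 0, 10, 20))

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            Table2x2(-1, 5, 5, 5)


class TestKS:
    def test_identical_samples(self):
        r = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_disjoint_supports(self):
        r = ks_two_sample([1, 2, 3], [4, 5, 6])
        assert r.statistic == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            ks_two_sample([], [1.0])

    def test_statistic_matches_brute_force_and_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            nx, ny = rng.integers(5, 100, 2)
            x = np.round(rng.normal(size=nx), 1)  # rounding forces ties
            y = np.round(rng.normal(0.3, 1.1, size=ny), 1)
            r = ks_two_sample(x, y)
            # brute force: sup over every pooled threshold
            brute = max(
                abs(np.mean(x <= t) - np.mean(y <= t)) for t in np.concatenate([x, y])
            )
            assert abs(r.statistic - brute) < 1e-10
            assert abs(r.statistic - sps.ks_2samp(x, y).statistic) < 1e-10
            n_eff = nx * ny / (nx + ny)
            assert abs(r.p_value - kolmogorov(np.sqrt(n_eff) * r.statistic)) < 1e-8

    def test_symmetry_and_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=40), rng.normal(0.5, 1, size=60)
        d = ks_two_sample(x, y).statistic
        assert ks_two_sample(y, x).statistic == d
        assert ks_two_sample(np.exp(x), np.exp(y)).statistic == pytest.approx(d, abs=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p_in, p_out",
        [
            ([0.001], [0.001]),
            ([0.01, 0.5], [0.02, 1.0]),
            ([0.0004 / 73] * 73, [0.0004] * 73),
        ],
    )
    def test_closed_form(self, p_in, p_out):
        assert bonferroni(p_in) == pytest.approx(p_out, abs=1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bonferroni([0.2, 1.4])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    def test_monotone(self, ps):
        adj = bonferroni(ps)
        order = np.argsort(ps)
        assert all(
            adj[order[i]] <= adj[order[i + 1]] + 1e-15 for i in range(len(ps) - 1)
        )


class TestLogistic:
    def test_intercept_only_closed_form(self):
        y = np.zeros(5000)
        y[: int(0.54 * 5000)] = 1
        m = fit_logistic(np.empty((5000, 0)), y)
        assert m.converged
        assert m.intercept == pytest.approx(np.log(0.54 / 0.46), abs=1e-8)

    def test_single_binary_feature_recovers_log_odds_ratio(self):
        # exposed: 30 successes / 70 failures; unexposed: 50 / 50
        x = np.concatenate([np.ones(100), np.zeros(100)])[:, None]
        y = np.concatenate([np.ones(30), np.zeros(70), np.ones(50), np.zeros(50)])
        m = fit_logistic(x, y)
        assert m.coefficients[0] == pytest.approx(np.log((30 / 70) / (50 / 50)), abs=1e-6)
        assert m.intercept == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_and_statsmodels_agreement(self):
        rng = np.random.default_rng(4)
        n, beta, intercept = 5000, np.array([0.8, -0.5, 0.3, 0.0]), -0.2
        X = rng.normal(size=(n, 4))
        p = 1 / (1 + np.exp(-(intercept + X @ beta)))
        y = (rng.random(n) < p).astype(float)
        m = fit_logistic(X, y)
        assert m.converged
        import statsmodels.api as sm

        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        se = ref.bse
        assert abs(m.intercept - intercept) < 3 * se[0]
        for j in range(4):
            assert abs(m.coefficients[j] - beta[j]) < 3 * se[j + 1]
            assert m.coefficients[j] == pytest.approx(ref.params[j + 1], abs=1e-6)

    def test_deviance_is_non_increasing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(500, 3))
        y = (rng.random(500) < 0.4).astype(float)
        m = fit_logistic(X, y)
        path = np.array(m.deviance_path)
        assert np.all(np.diff(path) <= 1e-9)

    def test_fitted_mean_equals_observed_rate(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(800, 2))
        y = (rng.random(800) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        m = fit_logistic(X, y)
        fitted = predict_probability(m, X)
        assert abs(fitted.mean() - y.mean()) < 1e-6

    def test_perfect_separation_is_flagged_not_raised(self):
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])[:, None]
        y = np.concatenate([np.zeros(20), np.ones(20)])
        m = fit_logistic(x, y)
        assert not m.converged

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValidationError, match="no variation"):
            fit_logistic(np.zeros((10, 1)), np.ones(10))

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(7)
        x0 = rng.normal(size=200)
        X = np.column_stack([x0, 2 * x0, rng.normal(size=200)])
        y = (rng.random(200) < 0.5).astype(float)
        with pytest.raises(ValidationError, match="collinear"):
            fit_logistic(X, y)


class TestPredict:
    def test_zero_features_give_inverse_logit_of_intercept(self):
        y = np.concatenate([np.ones(30), np.zeros(70)])
        m = fit_logistic(np.empty((100, 0)), y)
        assert predict_probability(m, np.empty(0)) == pytest.approx(0.3, abs=1e-8)

    def test_hand_inverse_logit(self):
        x = np.concatenate([np.ones(100), np.zeros(100)])[:, None]
        y = np.concatenate([np.ones(30), np.zeros(70), np.ones(50), np.zeros(50)])
        m = fit_logistic(x, y)
        eta = m.intercept + m.coefficients[0]
        assert predict_probability(m, np.array([1.0])) == pytest.approx(
            1 / (1 + np.exp(-eta)), abs=1e-10
        )

    def test_length_mismatch_rejected(self):
        y = np.concatenate([np.ones(30), np.zeros(70)])
        m = fit_logistic(np.ones((100, 1)) * np.linspace(-1, 1, 100)[:, None], y)
        with pytest.raises(ValidationError):
            predict_probability(m, np.array([1.0, 2.0]))
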