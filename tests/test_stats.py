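"""Statistical operations against closed forms and independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from scipy.special import gammaln

from mvq.stats import (
    SeparationError,
    backward_stepwise_logistic,
    bonferroni_adjust,
    dichotomize_at_median,
    fisher_exact,
    fit_logistic,
    icc,
    natural_log_transform,
    partial_pearson,
    two_sample_t_test,
)


class TestLogTransform:
    def test_known_values(self):
        out = natural_log_transform([1.0, math.e])
        assert out[0] == pytest.approx(0.0)
        assert out[1] == pytest.approx(1.0)

    def test_lognormal_sample_symmetrized(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(3.0, 0.8, 5000)
        skew = sps.skew(natural_log_transform(x))
        assert abs(skew) < 0.2

    def test_zero_rejected_naming_row(self):
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            natural_log_transform([2.0, 0.0, 3.0])


class TestDichotomize:
    def test_even_split(self):
        labels, cutoff = dichotomize_at_median([1.0, 2.0, 3.0, 4.0])
        assert cutoff == 2.5
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_value_at_cutoff_goes_low(self):
        labels, cutoff = dichotomize_at_median([1.0, 2.0, 2.0, 5.0])
        assert cutoff == 2.0
        assert labels.tolist() == ["low", "low", "low", "high"]

    def test_25_ml_style_cutoff(self):
        vals = np.array([10.0, 20.0, 25.0, 30.0, 40.0])
        labels, cutoff = dichotomize_at_median(vals)
        assert cutoff == 25.0
        assert (labels == "low").sum() == 3  # <= 25 ml group

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            dichotomize_at_median([3.0, 3.0, 3.0])


class TestPartialPearson:
    def test_reduces_to_plain_pearson_without_covariates(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=50), rng.normal(size=50)
        res = partial_pearson(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r_partial == pytest.approx(r_ref)
        assert res.p_value == pytest.approx(p_ref, rel=1e-6)

    def test_perfect_linear_dependence(self):
        res = partial_pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r_partial == pytest.approx(1.0)

    def test_trivariate_normal_matches_matrix_closed_form(self):
        r_xy, r_xz, r_yz = 0.62, 0.4, 0.3
        cov = np.array([[1, r_xy, r_xz], [r_xy, 1, r_yz], [r_xz, r_yz, 1]])
        target = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        rng = np.random.default_rng(2)
        n = 2000
        sample = rng.multivariate_normal(np.zeros(3), cov, size=n)
        res = partial_pearson(sample[:, 0], sample[:, 1], sample[:, 2:])
        se = 1.0 / math.sqrt(n - 1 - 3)
        z = np.arctanh(res.r_partial)
        assert np.tanh(z - 1.96 * se) < target < np.tanh(z + 1.96 * se)

    def test_equals_pearson_of_ols_residuals(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=(100, 2))
        x = z @ [0.5, -0.2] + rng.normal(size=100)
        y = z @ [0.1, 0.7] + rng.normal(size=100)
        res = partial_pearson(x, y, z)
        design = np.column_stack([np.ones(100), z])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        assert res.r_partial == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=(30, 1))
        cov = pd.DataFrame({"a": z[:, 0], "b": 2 * z[:, 0]})
        with pytest.raises(ValueError, match="collinear"):
            partial_pearson(rng.normal(size=30), rng.normal(size=30), cov)

    def test_insufficient_df_rejected(self):
        with pytest.raises(ValueError, match="need n"):
            partial_pearson([1, 2, 3, 4], [1, 2, 3, 4], np.ones((4, 3)))


class TestTTest:
    def test_identical_groups_define_t0_p1(self):
        t, df, p = two_sample_t_test([5.0, 5.0, 5.0], [5.0, 5.0])
        assert t == 0.0 and p == 1.0

    def test_separated_jittered_constants(self):
        rng = np.random.default_rng(5)
        a = np.zeros(4) + rng.normal(0, 1e-6, 4)
        b = np.ones(4) + rng.normal(0, 1e-6, 4)
        _, _, p = two_sample_t_test(a, b)
        assert p < 1e-4

    def test_matches_scipy_welch_and_pooled(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 20), rng.normal(0.3, 2, 25)
        for equal_var in (False, True):
            t, df, p = two_sample_t_test(a, b, equal_var=equal_var)
            ref = sps.ttest_ind(a, b, equal_var=equal_var)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(7)
        reps, n = 10_000, 30
        a = rng.normal(size=(reps, n))
        b = rng.normal(size=(reps, n))
        p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
        rate = float((p < 0.05).mean())
        assert 0.04 <= rate <= 0.06


def _brute_force_fisher(table):
    """Independent oracle: itertools enumeration of all tables with the
    observed margins, probability method."""
    obs = np.asarray(table)
    rows, cols = obs.sum(1), obs.sum(0)
    n = obs.sum()

    def log_p(t):
        return (
            gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
            - gammaln(n + 1) - gammaln(np.asarray(t) + 1.0).sum()
        )

    lp_obs = log_p(obs)
    total = 0.0
    r, c = obs.shape
    ranges = [range(min(rows[i], cols[j]) + 1) for i in range(r - 1) for j in range(c - 1)]
    for cells in itertools.product(*ranges):
        t = np.zeros((r, c), dtype=int)
        t[: r - 1, : c - 1] = np.reshape(cells, (r - 1, c - 1))
        t[: r - 1, c - 1] = rows[: r - 1] - t[: r - 1, : c - 1].sum(1)
        t[r - 1, :] = cols - t[: r - 1, :].sum(0)
        if (t < 0).any():
            continue
        lp = log_p(t)
        if lp <= lp_obs + 1e-9 * abs(lp_obs) + 1e-12:
            total += math.exp(lp)
    return min(total, 1.0)


class TestFisherExact:
    def test_documented_2x2_example(self):
        assert fisher_exact([[3, 1], [1, 3]]) == pytest.approx(0.4857, abs=5e-5)

    def test_identical_rows_give_p_one(self):
        assert fisher_exact([[4, 6], [4, 6]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_scipy_on_random_2x2(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 12, size=(2, 2))
        if t.sum() == 0:
            t[0, 0] = 1
        assert fisher_exact(t) == pytest.approx(sps.fisher_exact(t)[1], rel=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_2x3(self, seed):
        rng = np.random.default_rng(100 + seed)
        t = rng.integers(0, 8, size=(2, 3))
        if t.sum() == 0:
            t[0, 0] = 1
        assert fisher_exact(t) == pytest.approx(_brute_force_fisher(t), rel=1e-9)

    def test_oversized_table_rejected(self):
        with pytest.raises(ValueError, match="chi-square"):
            fisher_exact(np.ones((4, 4), dtype=int))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            fisher_exact([[1, -1], [2, 2]])


class TestLogistic:
    def test_intercept_only_recovers_log_odds(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        m = fit_logistic(y, np.zeros((100, 0)))
        assert m.table.loc["intercept", "estimate"] == pytest.approx(
            math.log(0.3 / 0.7), abs=1e-6
        )

    def test_two_by_two_odds_ratio_closed_form(self):
        a, b, c, d = 17, 12, 6, 24
        y = np.r_[np.ones(a + b), np.zeros(c + d)]
        x = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        m = fit_logistic(y, x[:, None])
        assert m.table.iloc[1]["or"] == pytest.approx(a * d / (b * c), rel=1e-6)

    def test_parameter_recovery_large_sample(self):
        rng = np.random.default_rng(8)
        n = 10_000
        X = rng.normal(size=(n, 2))
        beta = np.array([0.5, -0.8])
        p = 1 / (1 + np.exp(-(0.3 + X @ beta)))
        y = (rng.random(n) < p).astype(float)
        m = fit_logistic(y, X)
        for i, b in enumerate([0.3, *beta]):
            est, se = m.table.iloc[i][["estimate", "se"]]
            assert abs(est - b) < 3 * se

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(9)
        n = 500
        X = rng.normal(size=(n, 3))
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ [0.4, -0.2, 0.1])))).astype(float)
        ours = fit_logistic(y, X)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(ours.table["estimate"], ref.params, atol=1e-6)
        assert np.allclose(ours.table["se"], ref.bse, atol=1e-5)
        assert ours.log_likelihood == pytest.approx(ref.llf, rel=1e-8)

    def test_separation_detected(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = np.r_[np.ones(20), -np.ones(20)]
        with pytest.raises(SeparationError):
            fit_logistic(y, x[:, None])

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            fit_logistic(np.ones(10), np.random.default_rng(0).normal(size=(10, 1)))

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            fit_logistic(y, X)


def _simulate_candidates(seed, n=2000):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, 5)), columns=["age", "true", "noise1", "noise2", "noise3"]
    )
    eta = 0.2 * X["age"] + 1.0 * X["true"]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return y, X


class TestStepwise:
    def test_all_candidates_forced_returns_full_model(self):
        y, X = _simulate_candidates(0, n=400)
        m = backward_stepwise_logistic(
            y, X, forced=tuple(X.columns), screen_p=None
        )
        assert set(m.terms) == set(X.columns)
        assert m.removal_trace == []

    def test_forced_variable_never_removed(self):
        for seed in range(5):
            y, X = _simulate_candidates(seed, n=600)
            m = backward_stepwise_logistic(y, X, forced=("age",), screen_p=None)
            assert "age" in m.terms
            assert all(t != "age" for t, _, _ in m.removal_trace)

    def test_true_predictor_retained_noise_mostly_dropped(self):
        y, X = _simulate_candidates(42)
        m = backward_stepwise_logistic(y, X, forced=("age",),
                                       always_include=("true",), screen_p=0.1)
        assert "true" in m.terms

    def test_greedy_path_matches_brute_force_removal_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        y, X = _simulate_candidates(3, n=500)
        X = X[["age", "true", "noise1", "noise2"]]
        m = backward_stepwise_logistic(y, X, forced=("age",), screen_p=None)

        # independent re-execution of the greedy path with statsmodels
        def ll(terms):
            if terms:
                return sm.Logit(y, sm.add_constant(X[list(terms)])).fit(disp=0).llf
            return sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf

        current = list(X.columns)
        expected_trace = []
        while True:
            removable = [t for t in current if t != "age"]
            full_ll = ll(current)
            pvals = {
                t: sps.chi2.sf(2 * (full_ll - ll([u for u in current if u != t])), 1)
                for t in removable
            }
            worst = max(pvals, key=lambda t: pvals[t])
            if pvals[worst] <= 0.10:
                break
            expected_trace.append(worst)
            current.remove(worst)
        assert [t for t, _, _ in m.removal_trace] == expected_trace
        assert sorted(m.terms) == sorted(current)


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.tile(np.arange(10.0)[:, None], (1, 3))
        assert icc(x, "agreement").icc == pytest.approx(1.0)
        assert icc(x, "consistency").icc == pytest.approx(1.0)

    def test_constant_shift_breaks_agreement_not_consistency(self):
        x = np.arange(10.0)[:, None]
        ratings = np.hstack([x, x + 5.0])
        assert icc(ratings, "consistency").icc == pytest.approx(1.0)
        assert icc(ratings, "agreement").icc < 1.0

    def test_variance_components_recovered_in_simulation(self):
        rng = np.random.default_rng(11)
        n, k = 5000, 3
        subj = rng.normal(0, 3.0, (n, 1))
        # fixed rater offsets with unit sample variance, so the rater
        # component is not itself a 3-draw random quantity
        rater = np.array([[-1.0, 0.0, 1.0]])
        err = rng.normal(0, 1.0, (n, k))
        res = icc(subj + rater + err, "agreement")
        assert res.icc == pytest.approx(9.0 / 11.0, abs=0.02)
        assert res.var_subjects == pytest.approx(9.0, rel=0.1)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        n, k = 30, 3
        data = rng.normal(0, 2, (n, 1)) + rng.normal(0, 1, (n, k))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": data.ravel(),
        })
        ref = pg.intraclass_corr(long, "subject", "rater", "score")
        ours_a = icc(data, "agreement").icc
        ours_c = icc(data, "consistency").icc
        assert ours_a == pytest.approx(
            float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0]), abs=1e-6
        )
        assert ours_c == pytest.approx(
            float(ref.loc[ref.Type == "ICC(C,1)", "ICC"].iloc[0]), abs=1e-6
        )

    def test_constant_ratings_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc(np.full((10, 2), 3.0))


class TestBonferroni:
    def test_single_p_unchanged(self):
        assert bonferroni_adjust([0.01])[0] == pytest.approx(0.01)

    def test_capped_adjustment(self):
        out = bonferroni_adjust([0.02, 0.03, 0.5])
        assert np.allclose(out, [0.06, 0.09, 1.0])

    def test_order_preserving(self):
        rng = np.random.default_rng(13)
        p = np.sort(rng.random(10))
        out = bonferroni_adjust(p)
        assert (np.diff(out) >= 0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5, 1.2])
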