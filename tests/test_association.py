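"""Residualization, adjusted correlations, bootstrap comparison, Holm, power."""

import numpy as np
import pytest
from scipy import stats

from wmprecision.association import (
    adjusted_association,
    compare_dependent_correlations,
    holm_bonferroni,
    required_sample_size,
    residualize,
)


def _partial_corr_recursive(x, y, Z):
    """Textbook recursive partial-correlation oracle."""
    if Z.shape[1] == 0:
        return np.corrcoef(x, y)[0, 1]
    z, Zr = Z[:, -1], Z[:, :-1]
    rxy = _partial_corr_recursive(x, y, Zr)
    rxz = _partial_corr_recursive(x, z, Zr)
    ryz = _partial_corr_recursive(y, z, Zr)
    return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))


def _brute_holm(p, alpha):
    """Literal step-down: sorted comparison with alpha/(m-i), cumulative-max adjustment."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            reject[idx] = True
        else:
            break
    adj = np.zeros(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adj[idx] = min(1.0, running)
    return reject, adj


class TestResidualize:
    def test_perfect_linear_fit_leaves_zero_residuals(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = 2.0 + X @ [1.5, -0.7]
        assert np.max(np.abs(residualize(y, X))) < 1e-10

    def test_no_covariates_is_centering(self):
        y = np.array([1.0, 2.0, 6.0])
        np.testing.assert_allclose(residualize(y, None), y - y.mean())

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 2))
        y = rng.normal(size=50)
        D = np.column_stack([np.ones(50), X])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        np.testing.assert_allclose(residualize(y, X), y - D @ beta, atol=1e-9)

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 3))
        r = residualize(rng.normal(size=60), X)
        assert abs(r.sum()) < 1e-8
        assert np.max(np.abs(X.T @ r)) < 1e-8

    def test_rank_deficiency_raises(self):
        X = np.ones((20, 2))  # duplicate of the intercept
        with pytest.raises(ValueError):
            residualize(np.arange(20.0), X)


class TestAdjustedAssociation:
    def test_self_correlation(self):
        x = np.arange(10.0)
        res = adjusted_association(x, x, covariates=None)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12
        assert res.df == 8

    def test_empty_covariates_equals_plain_pearson(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 40))
        res = adjusted_association(x, y, covariates=None, mode="residualize_x_only")
        r_ref, p_ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
        assert res.p == pytest.approx(p_ref, rel=1e-9)

    def test_residualize_both_equals_partial_correlation_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            X = rng.normal(size=(60, 2))
            x = rng.normal(size=60) + X @ [0.5, -0.2]
            y = rng.normal(size=60) + X @ [0.3, 0.4]
            res = adjusted_association(x, y, X, mode="residualize_both")
            assert res.r == pytest.approx(_partial_corr_recursive(x, y, X), abs=1e-9)
            assert res.df == 60 - 2 - 2

    def test_residualize_both_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(80, 4)), columns=["x", "y", "c1", "c2"])
        res = adjusted_association(
            df["x"], df["y"], df[["c1", "c2"]].to_numpy(), mode="residualize_both"
        )
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)

    def test_cohort_scale_parameter_recovery(self):
        # adjusted correlation built into the generative model is recovered
        # within the Fisher-z band at n=500
        rng = np.random.default_rng(6)
        n = 500
        cov = rng.normal(size=(n, 2))
        latent = rng.normal(size=n)
        x = latent + 0.1 * cov[:, 0] + 0.1 * cov[:, 1] + rng.normal(size=n) * np.sqrt(1 / 0.25 - 1)
        y = latent  # corr(latent-part of x, y) = 0.5 by construction of x's noise
        res = adjusted_association(x, y, cov, mode="residualize_x_only")
        assert res.r == pytest.approx(0.5, abs=0.08)

    def test_too_few_cases_raise(self):
        with pytest.raises(ValueError):
            adjusted_association([1, 2, 3], [1, 2, 3])


class TestCompareDependentCorrelations:
    def test_identical_variables_report_no_difference(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=(2, 40))
        c = compare_dependent_correlations(x, y, y, n_resamples=200, seed=1)
        assert c.t_stat == 0.0 and c.p_t == 1.0 and c.p_percentile == 1.0
        assert c.diff_mean == 0.0

    def test_swapping_outcomes_negates_t_and_preserves_p(self):
        rng = np.random.default_rng(8)
        x, y1, y2 = rng.normal(size=(3, 50))
        a = compare_dependent_correlations(x, y1, y2, n_resamples=500, seed=3)
        b = compare_dependent_correlations(x, y2, y1, n_resamples=500, seed=3)
        assert a.t_stat == pytest.approx(-b.t_stat)
        assert a.p_t == pytest.approx(b.p_t)
        assert a.p_percentile == pytest.approx(b.p_percentile)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        x, y1, y2 = rng.normal(size=(3, 30))
        a = compare_dependent_correlations(x, y1, y2, n_resamples=300, seed=5)
        b = compare_dependent_correlations(x, y1, y2, n_resamples=300, seed=5)
        assert a.as_dict() == b.as_dict()

    def test_detects_truly_different_associations(self):
        # power under rho1=0.5, rho2=0.0 at n=50: percentile p < .05 in >= 70%
        rng = np.random.default_rng(10)
        L = np.linalg.cholesky(np.array([[1, 0.5, 0.0], [0.5, 1, 0.15], [0.0, 0.15, 1]]))
        hits = 0
        n_sims = 300
        for s in range(n_sims):
            Z = rng.standard_normal((50, 3)) @ L.T
            c = compare_dependent_correlations(Z[:, 0], Z[:, 1], Z[:, 2], n_resamples=500, seed=s)
            hits += c.p_percentile < 0.05
        assert hits / n_sims >= 0.70

    def test_preconditions(self):
        x = np.arange(5.0)
        with pytest.raises(ValueError):
            compare_dependent_correlations(x, x, x, n_resamples=500)
        x = np.random.default_rng(0).normal(size=20)
        with pytest.raises(ValueError):
            compare_dependent_correlations(x, x, x, n_resamples=50)


class TestHolm:
    def test_worked_example(self):
        reject, adj = holm_bonferroni([0.01, 0.04, 0.03], alpha=0.05)
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])
        assert list(reject) == [True, False, False]

    def test_single_comparison_is_raw_test(self):
        reject, adj = holm_bonferroni([0.04], alpha=0.05)
        assert reject[0] and adj[0] == pytest.approx(0.04)

    def test_all_ones_never_reject(self):
        reject, adj = holm_bonferroni([1.0, 1.0, 1.0], alpha=0.05)
        assert not reject.any() and (adj == 1.0).all()

    def test_matches_brute_force_step_down(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            m = rng.integers(1, 6)
            p = rng.uniform(0, 1, m)
            reject, adj = holm_bonferroni(p, alpha=0.05)
            ref_reject, ref_adj = _brute_holm(p, 0.05)
            np.testing.assert_array_equal(reject, ref_reject)
            np.testing.assert_allclose(adj, ref_adj, atol=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            holm_bonferroni([])
        with pytest.raises(ValueError):
            holm_bonferroni([1.2])


class TestPower:
    def test_published_design_point(self):
        # r = 0.40, two-tailed alpha 0.05, power 0.80 -> 47 (consistent with
        # the "around 50" design rule)
        assert required_sample_size(0.40, 0.05, 0.80) == 47

    def test_near_perfect_correlation_floors_at_four(self):
        assert required_sample_size(0.999999, 0.05, 0.80) == 4

    def test_nonincreasing_in_effect_size(self):
        ns = [required_sample_size(r, 0.05, 0.80) for r in np.linspace(0.05, 0.95, 19)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_bounds_rejected(self):
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                required_sample_size(bad)
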