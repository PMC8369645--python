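import numpy as np
import pytest

from txwas.lmm import AssociationResult
from txwas.penalized import (
    BootstrapSpec,
    PenaltySpec,
    TuningCurve,
    bootstrap_wald,
    cv_curve,
    declare_candidates,
    fit_penalized,
    lambda_max,
    select_alpha,
    select_tuning,
)


def random_instance(n, m, seed, signal=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, m))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    y = rng.standard_normal(n)
    if signal is not None:
        for j, b in signal:
            y = y + b * X[:, j]
    return X, y


class TestFitPenalized:
    def test_unpenalized_limit_is_ols(self):
        X, y = random_instance(50, 8, seed=0, signal=[(0, 1.0)])
        coef, intercept = fit_penalized(y, X, PenaltySpec(alpha=1.0, lam=0.0))
        Xc = X - X.mean(axis=0)
        expected = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        assert np.allclose(coef, expected, atol=1e-6)

    def test_ridge_matches_closed_form_hand_instance(self):
        X, y = random_instance(10, 5, seed=1)
        lam = 0.37
        coef, _ = fit_penalized(y, X, PenaltySpec(alpha=0.0, lam=lam))
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        expected = np.linalg.solve(Xc.T @ Xc + 10 * lam * np.eye(5), Xc.T @ yc)
        assert np.allclose(coef, expected, atol=1e-8)

    def test_ridge_closed_form_on_100_random_instances(self):
        # includes over-determined and under-determined shapes
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = int(rng.integers(6, 30))
            m = int(rng.integers(2, 40))
            lam = float(rng.uniform(0.01, 2.0))
            X = rng.standard_normal((n, m))
            y = rng.standard_normal(n)
            coef, _ = fit_penalized(y, X, PenaltySpec(alpha=0.0, lam=lam))
            Xc, yc = X - X.mean(axis=0), y - y.mean()
            expected = np.linalg.solve(Xc.T @ Xc + n * lam * np.eye(m), Xc.T @ yc)
            assert np.allclose(coef, expected, atol=1e-8), f"seed {seed}"

    def test_lasso_orthonormal_soft_threshold(self):
        rng = np.random.default_rng(2)
        n, m = 40, 10
        Q, _ = np.linalg.qr(rng.standard_normal((n, m)))
        y = rng.standard_normal(n)
        lam = 0.02
        coef, _ = fit_penalized(y, Q, PenaltySpec(alpha=1.0, lam=lam),
                                fit_intercept=False, tol=1e-10)
        z = Q.T @ y                       # univariate OLS under orthonormality
        expected = np.sign(z) * np.maximum(np.abs(z) - n * lam, 0.0)
        assert np.allclose(coef, expected, atol=1e-8)

    def test_en_limits_match_lasso_and_ridge(self):
        X, y = random_instance(60, 30, seed=3, signal=[(0, 0.8), (5, -0.5)])
        lam = 0.05
        en1, _ = fit_penalized(y, X, PenaltySpec(alpha=1.0, lam=lam), tol=1e-10)
        lasso, _ = fit_penalized(y, X, PenaltySpec(alpha=1.0, lam=lam), tol=1e-10)
        assert np.array_equal(en1, lasso)
        en0, _ = fit_penalized(y, X, PenaltySpec(alpha=0.0, lam=lam))
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        ridge = np.linalg.solve(Xc.T @ Xc + 60 * lam * np.eye(30), Xc.T @ yc)
        assert np.allclose(en0, ridge, atol=1e-8)

    def test_lambda_at_or_above_lambda_max_zeroes_all(self):
        X, y = random_instance(50, 20, seed=4, signal=[(0, 1.0)])
        lmax = lambda_max(y, X, 1.0)
        Xc, yc = X - X.mean(axis=0), y - y.mean()
        assert lmax == pytest.approx(np.max(np.abs(Xc.T @ yc)) / 50, rel=1e-12)
        for lam in (lmax, 1.5 * lmax):
            coef, _ = fit_penalized(y, X, PenaltySpec(alpha=1.0, lam=lam))
            assert np.all(coef == 0.0)

    def test_l1_norm_nonincreasing_in_lambda(self):
        X, y = random_instance(60, 25, seed=5, signal=[(0, 1.0), (3, 0.6)])
        lmax = lambda_max(y, X, 1.0)
        lams = np.geomspace(lmax, 1e-3 * lmax, 30)
        norms = [np.abs(fit_penalized(y, X, PenaltySpec(1.0, lam))[0]).sum()
                 for lam in lams]
        assert all(a <= b + 1e-10 for a, b in zip(norms[:-1], norms[1:]))

    def test_nonconvergence_raises_with_iteration_count(self):
        X, y = random_instance(30, 60, seed=6, signal=[(i, 0.5) for i in range(10)])
        with pytest.raises(RuntimeError, match="converge"):
            fit_penalized(y, X, PenaltySpec(alpha=0.5, lam=1e-6),
                          tol=1e-14, max_iter=2)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PenaltySpec(alpha=1.2, lam=0.1)
        with pytest.raises(ValueError):
            PenaltySpec(alpha=0.5, lam=-1.0)


class TestCvCurve:
    def test_determinism_same_seed(self):
        X, y = random_instance(80, 40, seed=7, signal=[(0, 0.7)])
        a = cv_curve(y, X, 1.0, folds=5, seed=3)
        b = cv_curve(y, X, 1.0, folds=5, seed=3)
        assert np.array_equal(a.fold_assignment, b.fold_assignment)
        assert np.array_equal(a.cv_error, b.cv_error)
        assert np.array_equal(a.cv_se, b.cv_se)

    def test_null_response_favors_heavy_penalty(self):
        # under a pure-noise response the Min rule should land in the
        # largest-lambda decile of the grid most of the time
        hits = 0
        for seed in range(50):
            X, y = random_instance(80, 40, seed=200 + seed)
            curve = cv_curve(y, X, 1.0, folds=5, seed=seed)
            spec = select_tuning(curve, "min")
            rank = int(np.nonzero(curve.lambdas == spec.lam)[0][0])
            hits += rank < len(curve.lambdas) // 10
        assert hits >= 40

    def test_grid_top_is_lambda_max(self):
        X, y = random_instance(50, 20, seed=8, signal=[(0, 1.0)])
        curve = cv_curve(y, X, 1.0, folds=5, seed=0)
        assert curve.lambdas[0] == pytest.approx(lambda_max(y, X, 1.0), rel=1e-12)

    def test_too_small_fold_raises(self):
        X, y = random_instance(12, 5, seed=9)
        with pytest.raises(ValueError):
            cv_curve(y, X, 1.0, folds=11, seed=0)


class TestSelectTuning:
    def make_curve(self, errors, se_at_min):
        errors = np.asarray(errors, dtype=float)
        return TuningCurve(lambdas=np.geomspace(1.0, 0.01, len(errors)),
                           alpha=1.0, cv_error=errors,
                           cv_se=np.full(len(errors), se_at_min),
                           folds=5, seed=0)

    def test_band_excludes_larger_lambdas(self):
        # increasing error in decreasing lambda; 1SE band excludes the others
        curve = self.make_curve([1.0, 1.1, 1.3], 0.05)
        assert select_tuning(curve, "min").lam == curve.lambdas[0]
        assert select_tuning(curve, "one_se").lam == curve.lambdas[0]

    def test_band_includes_second_lambda(self):
        curve = self.make_curve([1.04, 1.0, 1.3][::1], 0.05)
        # construct: min at lambda_2 (error 1.0), lambda_1 error 1.04 <= 1.05
        errors = np.array([1.04, 1.0, 1.3])
        curve = self.make_curve(errors, 0.05)
        assert select_tuning(curve, "min").lam == curve.lambdas[1]
        assert select_tuning(curve, "one_se").lam == curve.lambdas[0]

    def test_flat_curve_picks_largest_lambda(self):
        curve = self.make_curve([1.0, 1.0, 1.0, 1.0], 0.0)
        assert select_tuning(curve, "one_se").lam == curve.lambdas[0]


class TestSelectAlpha:
    def test_single_alpha_returned(self):
        X, y = random_instance(60, 20, seed=10, signal=[(0, 0.8)])
        a, curve = select_alpha(y, X, alpha_grid=[0.5], folds=5, seed=1)
        assert a == 0.5 and curve.alpha == 0.5

    def test_folds_shared_across_alphas(self):
        X, y = random_instance(60, 20, seed=11)
        _, c1 = select_alpha(y, X, alpha_grid=[0.2, 0.8], folds=5, seed=2)
        c2 = cv_curve(y, X, 0.2, folds=5, seed=2)
        assert np.array_equal(c1.fold_assignment, c2.fold_assignment)

    def test_dense_small_effects_favor_small_alpha(self):
        # many small effects: ridge-like; selected alpha below the midpoint
        # of the grid in a clear majority of seeds
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(3000 + seed)
            X = rng.standard_normal((80, 60))
            X = (X - X.mean(0)) / X.std(0, ddof=1)
            b = rng.normal(0.0, 0.12, size=60)     # dense tiny effects
            y = X @ b + rng.standard_normal(80)
            a, _ = select_alpha(y, X, alpha_grid=[0.1, 0.3, 0.5, 0.7, 0.9],
                                folds=5, seed=seed)
            wins += a < 0.5
        assert wins >= 0.6 * n_seeds


class TestBootstrapWald:
    def test_determinism(self):
        X, y = random_instance(60, 15, seed=12, signal=[(0, 1.0)])
        spec = PenaltySpec(alpha=0.0, lam=0.1)
        boot = BootstrapSpec(n_boot=50, resample_size=40, seed=9)
        r1 = bootstrap_wald(y, X, spec, [0, 1, 2], boot)
        r2 = bootstrap_wald(y, X, spec, [0, 1, 2], boot)
        assert [r.p_value for r in r1] == [r.p_value for r in r2]

    def test_strong_gene_significant_null_gene_not_extreme(self):
        X, y = random_instance(120, 30, seed=13, signal=[(0, 1.0)])
        spec = PenaltySpec(alpha=0.0, lam=0.05)
        boot = BootstrapSpec(n_boot=200, resample_size=100, seed=4)
        res = bootstrap_wald(y, X, spec, [0, 7], boot)
        assert res[0].p_value < 0.05
        assert res[0].candidate
        assert res[1].p_value > res[0].p_value

    def test_empty_test_set_rejected(self):
        X, y = random_instance(30, 5, seed=14)
        with pytest.raises(ValueError):
            bootstrap_wald(y, X, PenaltySpec(0.0, 0.1), [], BootstrapSpec())


class TestDeclareCandidates:
    def make_results(self):
        from scipy.stats import chi2
        # Wald statistics 25, 4, 0.01 -> p ~ 5.7e-7, 0.0455, 0.92
        return [
            AssociationResult("g0", 0.5, 0.1, 25.0, float(chi2.sf(25.0, 1)), "EN-Min"),
            AssociationResult("g1", -0.2, 0.1, 4.0, float(chi2.sf(4.0, 1)), "EN-Min"),
            AssociationResult("g2", 0.01, 0.1, 0.01, float(chi2.sf(0.01, 1)), "EN-Min"),
            AssociationResult("g3", 0.0, None, None, None, "EN-Min"),
        ]

    def test_three_nonzero_two_significant(self):
        res = self.make_results()
        assert declare_candidates(res, "nonzero") == {"g0", "g1", "g2"}
        assert declare_candidates(res, "nonzero_wald") == {"g0", "g1"}

    def test_wald_subset_of_nonzero(self):
        res = self.make_results()
        assert declare_candidates(res, "nonzero_wald") <= declare_candidates(res, "nonzero")

    def test_all_zero_fit_empty_both_ways(self):
        res = [AssociationResult("g0", 0.0, None, None, None, "LASSO-1SE")]
        assert declare_candidates(res, "nonzero") == set()
        assert declare_candidates(res, "nonzero_wald") == set()

    def test_missing_pvalues_rejected(self):
        res = [AssociationResult("g0", 0.5, None, None, None, "LASSO-Min")]
        with pytest.raises(ValueError, match="bootstrap"):
            declare_candidates(res, "nonzero_wald")
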