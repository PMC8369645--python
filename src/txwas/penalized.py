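"""Multi-gene penalized regressions: LASSO, ridge, elastic net.

All three estimators minimize

    (1/(2n)) * ||y - mu - X b||^2 + lambda * [ alpha*|b|_1 + (1-alpha)/2*|b|_2^2 ]

with alpha = 1 the LASSO, alpha = 0 ridge regression, and 0 < alpha < 1 the
elastic net.  Textbook statements of the three objectives without the 1/(2n)
and 1/2 factors differ only by a reparameterization of lambda; this scaling is
the one used by glmnet and scikit-learn and is the convention documented and
tested here (`OBJECTIVE_CONVENTION`).

lambda (and alpha for the elastic net) are tuned by k-fold cross-validation
under two rules: "min" picks the lambda minimizing cross-validated mean
squared prediction error; "one_se" picks the largest lambda whose error is
within one standard error (fold-to-fold SD / sqrt(folds)) of that minimum —
the conservative choice.  Because the solvers do not provide var(b_i), Wald
tests use a bootstrap estimate of the coefficient variance at fixed tuning.

Solvers: coordinate descent via scikit-learn for alpha > 0; the exact
SVD/dual closed form for ridge (alpha = 0), for which coordinate descent has
no advantage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path

from .lmm import AssociationResult
from .preprocess import ExpressionMatrix

__all__ = ["PenaltySpec", "TuningCurve", "BootstrapSpec", "fit_penalized",
           "cv_curve", "select_tuning", "select_alpha", "lambda_max",
           "bootstrap_wald", "declare_candidates"]

OBJECTIVE_CONVENTION = "1/(2n)*RSS + lambda*(alpha*l1 + (1-alpha)/2*l2^2)"

# glmnet's floor on l1_ratio when computing the lambda grid for ridge
_ALPHA_FLOOR = 1e-3


@dataclass
class PenaltySpec:
    """One point in the penalty plane.  alpha mixes l1 (alpha=1, LASSO) and
    l2 (alpha=0, ridge); lambda is the overall penalty strength."""

    alpha: float
    lam: float
    objective_convention: str = OBJECTIVE_CONVENTION

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class TuningCurve:
    """Cross-validated MSE along a descending lambda grid at one alpha."""

    lambdas: np.ndarray
    alpha: float
    cv_error: np.ndarray
    cv_se: np.ndarray
    folds: int
    seed: int
    fold_assignment: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        self.cv_error = np.asarray(self.cv_error, dtype=float)
        self.cv_se = np.asarray(self.cv_se, dtype=float)
        if not (len(self.lambdas) == len(self.cv_error) == len(self.cv_se)):
            raise ValueError("curve arrays must have equal length")
        if np.any(np.diff(self.lambdas) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")
        if np.any(self.cv_se < 0):
            raise ValueError("cv_se must be non-negative")


@dataclass
class BootstrapSpec:
    """Bootstrap settings for the Wald variance: resamples of
    ``resample_size`` individuals drawn with replacement, ``n_boot`` times."""

    n_boot: int = 1000
    resample_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1 or self.resample_size < 1:
            raise ValueError("n_boot and resample_size must be positive")


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, dtype=float)


def _ridge_solve(Xc: np.ndarray, yc: np.ndarray, lam: float) -> np.ndarray:
    """Exact ridge coefficients under the documented scaling: the penalized
    normal equations are (X'X + n*lambda*I) b = X'y; solved in the dual when
    n < m."""
    n, m = Xc.shape
    c = n * lam
    if m <= n:
        return np.linalg.solve(Xc.T @ Xc + c * np.eye(m), Xc.T @ yc)
    G = Xc @ Xc.T + c * np.eye(n)
    return Xc.T @ np.linalg.solve(G, yc)


def fit_penalized(
    y: np.ndarray,
    X,
    spec: PenaltySpec,
    fit_intercept: bool = True,
    tol: float = 1e-6,
    max_iter: int = 10000,
) -> tuple[np.ndarray, float]:
    """Solve the penalized objective at (alpha, lambda); returns (coef, intercept).

    lambda = 0 reduces to least squares; alpha = 0 uses the ridge closed form;
    otherwise coordinate descent.  Non-convergence raises rather than warns.
    """
    Xv = _as_values(X)
    y = np.asarray(y, dtype=float)
    n = Xv.shape[0]
    if fit_intercept:
        x_mean, y_mean = Xv.mean(axis=0), float(y.mean())
        Xc, yc = Xv - x_mean, y - y_mean
    else:
        x_mean, y_mean = np.zeros(Xv.shape[1]), 0.0
        Xc, yc = Xv, y
    if spec.lam == 0.0:
        coef = np.linalg.lstsq(Xc, yc, rcond=None)[0]
    elif spec.alpha == 0.0:
        coef = _ridge_solve(Xc, yc, spec.lam)
    else:
        model = ElasticNet(alpha=spec.lam, l1_ratio=spec.alpha, fit_intercept=False,
                           tol=tol, max_iter=max_iter)
        with warnings.catch_warnings():
            warnings.filterwarnings("error", category=ConvergenceWarning)
            try:
                model.fit(Xc, yc)
            except ConvergenceWarning as exc:
                raise RuntimeError(
                    f"coordinate descent did not converge in {max_iter} iterations"
                ) from exc
        coef = model.coef_.copy()
    intercept = y_mean - float(x_mean @ coef)
    return coef, intercept


def lambda_max(y: np.ndarray, X, alpha: float, fit_intercept: bool = True) -> float:
    """Smallest lambda at which all coefficients are zero for the given alpha
    (KKT: max_j |x_j'(y - ybar)| / (n * max(alpha, 1e-3)))."""
    Xv = _as_values(X)
    y = np.asarray(y, dtype=float)
    yc = y - y.mean() if fit_intercept else y
    Xc = Xv - Xv.mean(axis=0) if fit_intercept else Xv
    n = Xv.shape[0]
    return float(np.max(np.abs(Xc.T @ yc)) / (n * max(alpha, _ALPHA_FLOOR)))


def _fold_ids(n: int, folds: int, seed: int) -> np.ndarray:
    """Fold assignment by seeded permutation into near-equal blocks."""
    if folds < 3:
        raise ValueError("folds must be >= 3")
    if n < folds:
        raise ValueError("need at least one sample per fold")
    perm = np.random.default_rng(seed).permutation(n)
    ids = np.empty(n, dtype=int)
    for k, chunk in enumerate(np.array_split(perm, folds)):
        if chunk.size < 2:
            raise ValueError(f"fold {k} has fewer than 2 samples")
        ids[chunk] = k
    return ids


def _path_predictions(Xtr, ytr, Xte, alpha, lams, tol):
    """Held-out predictions for every lambda on the grid (descending)."""
    x_mean, y_mean = Xtr.mean(axis=0), ytr.mean()
    Xc, yc = Xtr - x_mean, ytr - y_mean
    Xte_c = Xte - x_mean
    if alpha == 0.0:
        U, sig, Vt = np.linalg.svd(Xc, full_matrices=False)
        uty = U.T @ yc
        P = Xte_c @ Vt.T                      # n_test x rank
        shrink = sig[None, :] / (sig[None, :] ** 2 + Xc.shape[0] * lams[:, None])
        return y_mean + (shrink * uty[None, :]) @ P.T  # n_lambda x n_test
    with warnings.catch_warnings():
        # fold fits at CV tolerance need not converge to full precision
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = enet_path(Xc, yc, l1_ratio=alpha, alphas=lams, tol=tol)
    return y_mean + (Xte_c @ coefs).T          # n_lambda x n_test


def cv_curve(
    y: np.ndarray,
    X,
    alpha: float,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    tol: float = 1e-3,
    fold_assignment: np.ndarray | None = None,
) -> TuningCurve:
    """k-fold cross-validated MSE along a log-spaced lambda grid.

    The grid runs from the full-data lambda_max down ``n_lambda`` log-spaced
    steps to ``lambda_min_ratio * lambda_max``.  ``cv_se`` is the fold-to-fold
    SD of the fold MSEs divided by sqrt(folds).  ``fold_assignment`` may be
    supplied to share folds across alphas.
    """
    Xv = _as_values(X)
    y = np.asarray(y, dtype=float)
    n = Xv.shape[0]
    ids = _fold_ids(n, folds, seed) if fold_assignment is None else np.asarray(fold_assignment)
    lam_hi = lambda_max(y, Xv, alpha)
    lams = np.geomspace(lam_hi, lambda_min_ratio * lam_hi, n_lambda)
    fold_mse = np.empty((folds, n_lambda))
    for k in range(folds):
        te = ids == k
        preds = _path_predictions(Xv[~te], y[~te], Xv[te], alpha, lams, tol)
        fold_mse[k] = np.mean((preds - y[te][None, :]) ** 2, axis=1)
    return TuningCurve(
        lambdas=lams, alpha=alpha,
        cv_error=fold_mse.mean(axis=0),
        cv_se=fold_mse.std(axis=0, ddof=1) / np.sqrt(folds),
        folds=folds, seed=seed, fold_assignment=ids,
    )


def select_tuning(curve: TuningCurve, rule: str) -> PenaltySpec:
    """Pick lambda from a tuning curve by the "min" or "one_se" rule."""
    k_min = int(np.argmin(curve.cv_error))
    if rule == "min":
        return PenaltySpec(alpha=curve.alpha, lam=float(curve.lambdas[k_min]))
    if rule == "one_se":
        bound = curve.cv_error[k_min] + curve.cv_se[k_min]
        ok = np.nonzero(curve.cv_error <= bound)[0]
        # grid is descending in lambda, so the first qualifying index is the
        # largest qualifying lambda
        return PenaltySpec(alpha=curve.alpha, lam=float(curve.lambdas[ok[0]]))
    raise ValueError(f"unknown tuning rule {rule!r}")


def select_alpha(
    y: np.ndarray,
    X,
    alpha_grid=None,
    folds: int = 10,
    seed: int = 0,
    **cv_kwargs,
) -> tuple[float, TuningCurve]:
    """Cross-validate alpha for the elastic net with folds shared across the
    grid; returns the alpha with the smallest min-rule error and its curve."""
    if alpha_grid is None:
        alpha_grid = [round(0.1 * k, 1) for k in range(1, 10)]
    if len(alpha_grid) == 0:
        raise ValueError("alpha_grid must be non-empty")
    Xv = _as_values(X)
    ids = _fold_ids(Xv.shape[0], folds, seed)
    best = None
    for a in alpha_grid:
        curve = cv_curve(y, Xv, a, folds=folds, seed=seed,
                         fold_assignment=ids, **cv_kwargs)
        err = float(curve.cv_error.min())
        if best is None or err < best[0]:
            best = (err, a, curve)
    return best[1], best[2]


def bootstrap_wald(
    y: np.ndarray,
    X,
    spec: PenaltySpec,
    test_set,
    boot: BootstrapSpec,
    method: str = "RR",
    gene_ids: list[str] | None = None,
) -> list[AssociationResult]:
    """Wald tests with bootstrap coefficient variances at fixed tuning.

    Draws ``n_boot`` resamples with replacement, refits at the fixed
    (alpha, lambda), and uses the empirical variance of each coefficient
    across resamples as var(b_i).  The Wald numerator is the full-data
    estimate.  Significance threshold is p <= 0.05 (the joint model needs no
    multiplicity correction).  A resample with a constant gene column is
    redrawn (at most 10 times).
    """
    Xv = _as_values(X)
    y = np.asarray(y, dtype=float)
    n, m = Xv.shape
    test_set = list(test_set)
    if len(test_set) == 0:
        raise ValueError("test_set must be non-empty")
    if gene_ids is None:
        gene_ids = X.gene_ids if isinstance(X, ExpressionMatrix) else [
            f"g{i}" for i in range(m)
        ]
    coef_full, _ = fit_penalized(y, Xv, spec)
    rng = np.random.default_rng(boot.seed)
    size = min(boot.resample_size, n)
    boot_coefs = np.empty((boot.n_boot, len(test_set)))
    cd_model = None
    if spec.alpha > 0 and spec.lam > 0:
        cd_model = ElasticNet(alpha=spec.lam, l1_ratio=spec.alpha,
                              fit_intercept=False, tol=1e-5, max_iter=10000,
                              warm_start=True)
    for r in range(boot.n_boot):
        for attempt in range(11):
            idx = rng.integers(0, n, size=size)
            Xb = Xv[idx]
            if np.all(Xb.max(axis=0) > Xb.min(axis=0)):
                break
        else:
            raise RuntimeError(
                f"resample {r}: constant gene column after 10 redraws"
            )
        yb = y[idx]
        x_mean, y_mean = Xb.mean(axis=0), yb.mean()
        Xc, yc = Xb - x_mean, yb - y_mean
        if spec.lam == 0.0:
            coef = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        elif spec.alpha == 0.0:
            coef = _ridge_solve(Xc, yc, spec.lam)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                cd_model.fit(Xc, yc)
            coef = cd_model.coef_
        boot_coefs[r] = coef[test_set]
    var_b = boot_coefs.var(axis=0, ddof=1)
    results = []
    for j, gi in enumerate(test_set):
        b = float(coef_full[gi])
        if var_b[j] <= 0:
            results.append(AssociationResult(gene_ids[gi], b, None, None, None, method))
            continue
        w = b * b / var_b[j]
        p = float(chi2.sf(w, df=1))
        results.append(AssociationResult(
            gene_id=gene_ids[gi], effect=b, se=float(np.sqrt(var_b[j])),
            wald=float(w), p_value=p, method=method, candidate=bool(p <= 0.05),
        ))
    return results


def declare_candidates(results: list[AssociationResult], strategy: str) -> set[str]:
    """Candidate genes from one penalized fit.

    "nonzero": genes with a nonzero coefficient.  "nonzero_wald": that set
    intersected with bootstrap Wald p <= 0.05 (requires p-values present on
    every nonzero-coefficient result).
    """
    nonzero = [r for r in results if r.effect is not None and r.effect != 0.0]
    if strategy == "nonzero":
        return {r.gene_id for r in nonzero}
    if strategy == "nonzero_wald":
        missing = [r.gene_id for r in nonzero if r.p_value is None]
        if missing:
            raise ValueError(
                f"nonzero_wald requires bootstrap p-values; missing for {missing[:3]}"
            )
        return {r.gene_id for r in nonzero if r.p_value <= 0.05}
    raise ValueError(f"unknown strategy {strategy!r}")
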