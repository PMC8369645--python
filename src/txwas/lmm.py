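"""Per-gene linear mixed model association scan with an expression kinship.

Model for one tested gene:

    y = mu*1 + b_i X_i + a + e,    a ~ N(0, K sigma^2),  e ~ N(0, I sigma_e^2)

with K the expression kinship.  Writing delta = sigma^2 / sigma_e^2 and
rotating everything by the eigenvectors of K turns the covariance into
sigma_e^2 * diag(delta*s_j + 1), so for fixed delta the fit is weighted least
squares and the REML log-likelihood can be profiled over delta alone.  delta
is re-estimated per gene (exact Wald mode); a single null-model delta shared
across genes is available as a fast approximation.

The Wald statistic W_i = b_i^2 / var(b_i) is referred to chi-square with one
degree of freedom, and genome-wide significance uses Bonferroni alpha/m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .preprocess import ExpressionMatrix, KinshipMatrix

__all__ = ["LmmFit", "AssociationResult", "reml_fit", "lmm_scan",
           "bonferroni_threshold", "results_to_frame"]

_LOG_DELTA_LO, _LOG_DELTA_HI = -10.0, 10.0
_GRID_POINTS = 64


@dataclass
class LmmFit:
    """REML variance components on the rotated scale."""

    delta: float          # sigma^2 / sigma_e^2
    sigma2: float         # polygenic variance
    sigma2_e: float       # residual variance
    mu: float             # intercept
    loglik_reml: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")
        if not np.isfinite(self.loglik_reml):
            raise ValueError("REML log-likelihood is not finite")

    @property
    def heritability(self) -> float:
        """sigma^2 / (sigma^2 + sigma_e^2), the variance proportion of the
        polygenic term (well-defined only when K != I)."""
        return self.sigma2 / (self.sigma2 + self.sigma2_e)


@dataclass
class AssociationResult:
    """One gene's association summary (any method)."""

    gene_id: str
    effect: float | None
    se: float | None
    wald: float | None
    p_value: float | None
    method: str
    candidate: bool = False

    def __post_init__(self) -> None:
        if self.wald is not None and self.p_value is not None:
            expected = float(chi2.sf(self.wald, df=1))
            if abs(expected - self.p_value) > 1e-10:
                raise ValueError("p_value inconsistent with Wald statistic")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m for m single-gene tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def _reml_pieces(log_delta, s, W_rot, y_rot):
    """Weighted cross-products and REML criterion at one delta (single design)."""
    d = np.exp(log_delta) * s + 1.0
    w = 1.0 / d
    A = W_rot.T @ (w[:, None] * W_rot)
    c = W_rot.T @ (w * y_rot)
    yy = float(y_rot @ (w * y_rot))
    try:
        beta = np.linalg.solve(A, c)
    except np.linalg.LinAlgError:
        return None
    rss = yy - float(beta @ c)
    n, p = W_rot.shape
    if rss <= 0:
        return None
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return None
    ll = -0.5 * ((n - p) * np.log(rss / (n - p)) + np.sum(np.log(d)) + logdetA)
    return {"beta": beta, "rss": rss, "A": A, "loglik": ll, "d": d}


def reml_fit(y: np.ndarray, covariates: np.ndarray | None, K: KinshipMatrix) -> LmmFit:
    """Profile REML over log delta in [-10, 10]: 64-point grid, then bounded
    refinement around the best grid point.  ``covariates`` (n x c, without the
    intercept) are optional fixed effects alongside the intercept."""
    y = np.asarray(y, dtype=float)
    n = y.size
    s, U = K.eigenvalues, K.eigenvectors
    if np.any(~np.isfinite(s)):
        bad = int(np.argmax(~np.isfinite(s)))
        raise ValueError(f"non-finite kinship eigenvalue at index {bad}")
    W = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    W_rot = U.T @ W
    y_rot = U.T @ y

    grid = np.linspace(_LOG_DELTA_LO, _LOG_DELTA_HI, _GRID_POINTS)
    lls = np.full(grid.size, -np.inf)
    for k, ld in enumerate(grid):
        piece = _reml_pieces(ld, s, W_rot, y_rot)
        if piece is not None:
            lls[k] = piece["loglik"]
    if not np.any(np.isfinite(lls)):
        raise ValueError("REML likelihood is non-finite on the whole delta grid")
    # ties toward smaller delta: argmax returns the first (smallest) maximizer
    k0 = int(np.argmax(lls))
    lo = grid[max(k0 - 1, 0)]
    hi = grid[min(k0 + 1, grid.size - 1)]
    res = minimize_scalar(
        lambda ld: -(_reml_pieces(ld, s, W_rot, y_rot) or {"loglik": -np.inf})["loglik"],
        bounds=(lo, hi), method="bounded", options={"xatol": 1e-8},
    )
    ld_opt = float(res.x) if -res.fun >= lls[k0] else float(grid[k0])
    piece = _reml_pieces(ld_opt, s, W_rot, y_rot)
    delta = float(np.exp(ld_opt))
    p = W_rot.shape[1]
    sigma2_e = piece["rss"] / (n - p)
    return LmmFit(
        delta=delta,
        sigma2=delta * sigma2_e,
        sigma2_e=sigma2_e,
        mu=float(piece["beta"][0]),
        loglik_reml=float(piece["loglik"]),
    )


def _scan_grid(s, one_rot, X_rot, y_rot):
    """Vectorized REML profile over the delta grid for every gene at once.

    For the two-column design [1, x_g] the weighted normal equations are 2x2
    and solvable in closed form, so a full grid over delta costs O(grid * n * m).
    Returns per-gene best grid index and the grid.
    """
    grid = np.linspace(_LOG_DELTA_LO, _LOG_DELTA_HI, _GRID_POINTS)
    n = y_rot.size
    m = X_rot.shape[1]
    best_ll = np.full(m, -np.inf)
    best_k = np.zeros(m, dtype=int)
    X2 = X_rot * X_rot
    for k, ld in enumerate(grid):
        d = np.exp(ld) * s + 1.0
        w = 1.0 / d
        wo = w * one_rot
        a11 = float(one_rot @ wo)
        a12 = wo @ X_rot
        a22 = w @ X2
        c1 = float(y_rot @ wo)
        c2 = (w * y_rot) @ X_rot
        yy = float(y_rot @ (w * y_rot))
        det = a11 * a22 - a12 * a12
        with np.errstate(divide="ignore", invalid="ignore"):
            b_gene = (a11 * c2 - a12 * c1) / det
            b_int = (a22 * c1 - a12 * c2) / det
            rss = yy - b_int * c1 - b_gene * c2
            ll = -0.5 * ((n - 2) * np.log(rss / (n - 2)) + np.sum(np.log(d)) + np.log(det))
        ok = np.isfinite(ll) & (rss > 0) & (det > 0)
        improve = ok & (ll > best_ll)
        best_ll[improve] = ll[improve]
        best_k[improve] = k
    return grid, best_k, best_ll


def _gene_reml(ld, s, one_rot, x_rot, y_rot):
    """Per-gene REML criterion and Wald pieces at one log-delta (closed-form 2x2)."""
    n = y_rot.size
    d = np.exp(ld) * s + 1.0
    w = 1.0 / d
    wo = w * one_rot
    a11 = float(one_rot @ wo)
    a12 = float(wo @ x_rot)
    a22 = float(w @ (x_rot * x_rot))
    c1 = float(y_rot @ wo)
    c2 = float((w * y_rot) @ x_rot)
    yy = float(y_rot @ (w * y_rot))
    det = a11 * a22 - a12 * a12
    if det <= 0:
        return None
    b_gene = (a11 * c2 - a12 * c1) / det
    b_int = (a22 * c1 - a12 * c2) / det
    rss = yy - b_int * c1 - b_gene * c2
    if rss <= 0:
        return None
    ll = -0.5 * ((n - 2) * np.log(rss / (n - 2)) + np.sum(np.log(d)) + np.log(det))
    sigma2_e = rss / (n - 2)
    var_b = sigma2_e * a11 / det
    return {"loglik": ll, "b": b_gene, "var_b": var_b}


def lmm_scan(
    y: np.ndarray,
    X: ExpressionMatrix,
    K: KinshipMatrix,
    alpha: float = 0.05,
    m_tests: int | None = None,
    gene_subset: list[int] | None = None,
    refine: bool = True,
) -> list[AssociationResult]:
    """Single-gene LMM scan: per-gene REML delta, GLS effect, Wald chi2(1) p.

    ``m_tests`` sets the Bonferroni denominator (defaults to the number of
    genes in X, even when only a subset is scanned).  Genes collinear with the
    intercept after rotation are reported with NA fields rather than dropped.
    """
    if not X.standardized:
        raise ValueError("lmm_scan requires standardized expression")
    y = np.asarray(y, dtype=float)
    s, U = K.eigenvalues, K.eigenvectors
    one_rot = U.T @ np.ones(y.size)
    y_rot = U.T @ y
    idx = list(range(X.n_genes)) if gene_subset is None else list(gene_subset)
    X_rot = U.T @ X.values[:, idx]
    m = X.n_genes if m_tests is None else m_tests
    threshold = bonferroni_threshold(alpha, m)

    grid, best_k, best_ll = _scan_grid(s, one_rot, X_rot, y_rot)
    results: list[AssociationResult] = []
    for j, gi in enumerate(idx):
        gene_id = X.gene_ids[gi]
        x_rot = X_rot[:, j]
        if not np.isfinite(best_ll[j]):
            results.append(AssociationResult(gene_id, None, None, None, None, "LMM"))
            continue
        k0 = best_k[j]
        ld_opt = float(grid[k0])
        if refine:
            lo, hi = grid[max(k0 - 1, 0)], grid[min(k0 + 1, grid.size - 1)]
            res = minimize_scalar(
                lambda ld: -(_gene_reml(ld, s, one_rot, x_rot, y_rot)
                             or {"loglik": -np.inf})["loglik"],
                bounds=(lo, hi), method="bounded", options={"xatol": 1e-6},
            )
            if np.isfinite(res.fun) and -res.fun >= best_ll[j]:
                ld_opt = float(res.x)
        piece = _gene_reml(ld_opt, s, one_rot, x_rot, y_rot)
        if piece is None or piece["var_b"] <= 0:
            results.append(AssociationResult(gene_id, None, None, None, None, "LMM"))
            continue
        b = piece["b"]
        var_b = piece["var_b"]
        w_stat = b * b / var_b
        p = float(chi2.sf(w_stat, df=1))
        results.append(AssociationResult(
            gene_id=gene_id, effect=float(b), se=float(np.sqrt(var_b)),
            wald=float(w_stat), p_value=p, method="LMM",
            candidate=bool(p <= threshold),
        ))
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Long-format results table (one row per gene x method)."""
    return pd.DataFrame(
        [{"gene_id": r.gene_id, "effect": r.effect, "se": r.se, "wald": r.wald,
          "p_value": r.p_value, "method": r.method, "candidate": r.candidate}
         for r in results]
    )
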