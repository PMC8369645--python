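"""Pseudo-phenotype simulation benchmark of power and type-I error.

Protocol, per replicate: genes are first classified once into trait-relevant
and trait-neutral sets by an elastic-net (Min rule) analysis of the base
trait; two distinct genes are then drawn from the neutral set.  The first
("spiked") gene receives an effect b = sqrt(h/(1-h)) on the standardized
trait, so that it explains a proportion h of the pseudo-phenotype variance;
the second ("shuffled") gene has its expression column permuted across
individuals, making it a pure null probe that retains its marginal
distribution.  The pseudo-phenotype is re-standardized and every requested
method is run from scratch (tuning re-selected per replicate).  Power is the
fraction of replicates detecting the spiked gene; type-I error is the
fraction falsely detecting the shuffled gene.

Detection rules per method tag:

=============  =====================================================
LMM            Wald p <= alpha/m (Bonferroni over all m genes)
LASSO-Min      nonzero coefficient at the Min-rule lambda
LASSO-Min-P    nonzero coefficient and bootstrap Wald p <= 0.05
LASSO-1SE      nonzero coefficient at the one-SE-rule lambda
EN-Min(-P)     as LASSO, with alpha cross-validated
EN-1SE         nonzero coefficient
RR-Min/RR-1SE  bootstrap Wald p <= 0.05 (ridge keeps all genes)
=============  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .lmm import lmm_scan
from .penalized import cv_curve, fit_penalized, select_alpha, select_tuning
from .preprocess import ExpressionMatrix, compute_kinship, standardize_vector
from .synthetic import SyntheticDataset

__all__ = ["Scenario", "ScenarioOutcome", "DEFAULT_H_GRID", "DEFAULT_METHODS",
           "classify_genes", "effect_for_h", "make_pseudo", "run_scenario",
           "benchmark_table"]

# the 23 variance-proportion scenarios of the reference protocol
DEFAULT_H_GRID = (0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.08, 0.10, 0.12, 0.14,
                  0.16, 0.18, 0.20, 0.22, 0.24, 0.26, 0.28, 0.30, 0.34, 0.38,
                  0.42, 0.46, 0.50)

DEFAULT_METHODS = ("LMM", "LASSO-Min", "LASSO-1SE", "EN-Min", "EN-1SE",
                   "RR-Min", "RR-1SE")

# desk-scale alpha grid for per-replicate elastic-net tuning; the
# analysis-level default (0.1..0.9 by 0.1) applies outside the benchmark
_SCENARIO_ALPHA_GRID = (0.1, 0.5, 0.9)


@dataclass
class Scenario:
    """One variance-proportion scenario of the benchmark."""

    h: float
    n_replicates: int = 50
    methods: tuple[str, ...] = DEFAULT_METHODS
    seed: int = 0
    folds: int = 10
    alpha_grid: tuple[float, ...] = _SCENARIO_ALPHA_GRID
    n_boot: int = 200
    boot_size: int = 200
    lmm_alpha: float = 0.05
    restandardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.h < 1.0:
            raise ValueError("h must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be positive")
        known = set(DEFAULT_METHODS) | {"LASSO-Min-P", "EN-Min-P"}
        unknown = set(self.methods) - known
        if unknown:
            raise ValueError(f"unknown method tags: {sorted(unknown)}")


@dataclass
class ScenarioOutcome:
    """Empirical power and type-I error per method for one scenario.

    ``estimates`` holds each method's per-replicate estimate of the spiked
    gene's effect (for penalized methods, the shrunken coefficient), useful
    for quantifying shrinkage bias against the true effect sqrt(h/(1-h)).
    """

    h: float
    n_replicates: int
    power: dict[str, float] = field(default_factory=dict)
    type1: dict[str, float] = field(default_factory=dict)
    estimates: dict[str, list[float]] = field(default_factory=dict)


def effect_for_h(h: float) -> float:
    """Effect size (phenotype-SD units) of a unit-variance independent
    predictor that contributes a proportion h of the resulting variance:
    solves b^2/(1+b^2) = h, i.e. b = sqrt(h/(1-h))."""
    if h < 0 or h >= 1:
        raise ValueError("h must lie in [0, 1)")
    return float(np.sqrt(h / (1.0 - h)))


def classify_genes(
    y: np.ndarray,
    X: ExpressionMatrix,
    folds: int = 10,
    seed: int = 0,
    alpha_grid=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split genes into trait-relevant and trait-neutral sets by an
    elastic-net Min-rule fit of the base trait; returns (relevant, neutral)
    index arrays.  Errors if no gene is left neutral."""
    if not X.standardized:
        raise ValueError("classify_genes requires standardized expression")
    y = np.asarray(y, dtype=float)
    a, curve = select_alpha(y, X.values, alpha_grid=alpha_grid, folds=folds, seed=seed)
    spec = select_tuning(curve, "min")
    coef, _ = fit_penalized(y, X.values, spec)
    relevant = np.nonzero(coef != 0.0)[0]
    neutral = np.nonzero(coef == 0.0)[0]
    if neutral.size == 0:
        raise ValueError("no trait-neutral genes; cannot simulate")
    return relevant, neutral


def make_pseudo(
    y: np.ndarray,
    X: ExpressionMatrix,
    spike_gene: int,
    null_gene: int,
    h: float,
    rng: np.random.Generator,
    restandardize: bool = True,
) -> tuple[np.ndarray, ExpressionMatrix]:
    """Build one pseudo-dataset: spike ``spike_gene`` onto the standardized
    trait at variance proportion h, permute ``null_gene``'s column."""
    if spike_gene == null_gene:
        raise ValueError("spike and null genes must be distinct")
    y_std = standardize_vector(np.asarray(y, dtype=float))
    b = effect_for_h(h)
    y_star = y_std + b * X.values[:, spike_gene]
    if restandardize:
        y_star = standardize_vector(y_star)
    V = X.values.copy()
    V[:, null_gene] = rng.permutation(V[:, null_gene])
    X_new = ExpressionMatrix(values=V, gene_ids=list(X.gene_ids),
                             sample_ids=list(X.sample_ids), standardized=X.standardized)
    return y_star, X_new


def _rr_bootstrap_pvals(y, Xv, specs, test_idx, full_coefs, n_boot, size, rng):
    """Bootstrap Wald p-values for ridge at several fixed lambdas, sharing the
    resamples (and each resample's Gram matrix) across lambdas.  Only the
    coefficients of ``test_idx`` are tracked."""
    n = Xv.shape[0]
    size = min(size, n)
    eye = np.eye(size)
    boots = {name: np.empty((n_boot, len(test_idx))) for name in specs}
    for r in range(n_boot):
        for attempt in range(11):
            idx = rng.integers(0, n, size=size)
            Xb = Xv[idx]
            if np.all(Xb.max(axis=0) > Xb.min(axis=0)):
                break
        else:
            raise RuntimeError(f"resample {r}: constant gene column after 10 redraws")
        yb = y[idx]
        Xc = Xb - Xb.mean(axis=0)
        yc = yb - yb.mean()
        G = Xc @ Xc.T
        Xt = Xc[:, test_idx]
        for name, spec in specs.items():
            dual = np.linalg.solve(G + size * spec.lam * eye, yc)
            boots[name][r] = Xt.T @ dual
    out = {}
    for name, spec in specs.items():
        var_b = boots[name].var(axis=0, ddof=1)
        b = full_coefs[name][test_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            w = b * b / var_b
        out[name] = chi2.sf(w, df=1)
    return out


def _cd_bootstrap_pvals(y, Xv, spec, test_idx, full_coef, n_boot, size, rng):
    """Bootstrap Wald p-values for a coordinate-descent spec (LASSO/EN) at
    fixed tuning, tracking only ``test_idx`` coefficients."""
    import warnings
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import ElasticNet

    n = Xv.shape[0]
    size = min(size, n)
    model = ElasticNet(alpha=spec.lam, l1_ratio=spec.alpha, fit_intercept=False,
                       tol=1e-5, max_iter=10000, warm_start=True)
    boots = np.empty((n_boot, len(test_idx)))
    for r in range(n_boot):
        for attempt in range(11):
            idx = rng.integers(0, n, size=size)
            Xb = Xv[idx]
            if np.all(Xb.max(axis=0) > Xb.min(axis=0)):
                break
        else:
            raise RuntimeError(f"resample {r}: constant gene column after 10 redraws")
        yb = y[idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Xb - Xb.mean(axis=0), yb - yb.mean())
        boots[r] = model.coef_[test_idx]
    var_b = boots.var(axis=0, ddof=1)
    b = full_coef[test_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = b * b / var_b
    return chi2.sf(w, df=1)


def _replicate_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(7, rep)))


def run_scenario(
    dataset: SyntheticDataset,
    scenario: Scenario,
    neutral: np.ndarray | None = None,
    trait: str | None = None,
) -> ScenarioOutcome:
    """Run one scenario: per replicate, draw a fresh (spike, null) pair from
    the neutral set, build the pseudo-data, run every requested method, and
    tally detections of the spiked (power) and shuffled (type-I) genes."""
    X = dataset.expression
    y = dataset.phenotypes[trait or dataset.phenotypes.columns[0]].to_numpy()
    if neutral is None:
        _, neutral = classify_genes(y, X, folds=scenario.folds, seed=scenario.seed,
                                    alpha_grid=scenario.alpha_grid)
    methods = list(scenario.methods)
    hits_spike = {tag: 0 for tag in methods}
    hits_null = {tag: 0 for tag in methods}
    estimates = {tag: [] for tag in methods}
    m = X.n_genes
    for rep in range(scenario.n_replicates):
        rng = _replicate_rng(scenario.seed, rep)
        spike, null = rng.choice(neutral, size=2, replace=False)
        spike, null = int(spike), int(null)
        y_star, X_new = make_pseudo(y, X, spike, null, scenario.h, rng,
                                    restandardize=scenario.restandardize)
        Xv = X_new.values
        detected = _analyze_replicate(
            y_star, X_new, Xv, spike, null, methods, scenario, m, rng,
        )
        for tag in methods:
            hits_spike[tag] += detected[tag][0]
            hits_null[tag] += detected[tag][1]
            estimates[tag].append(detected[tag][2])
    n_rep = scenario.n_replicates
    return ScenarioOutcome(
        h=scenario.h, n_replicates=n_rep,
        power={t: hits_spike[t] / n_rep for t in methods},
        type1={t: hits_null[t] / n_rep for t in methods},
        estimates=estimates,
    )


def _analyze_replicate(y_star, X_new, Xv, spike, null, methods, scenario, m, rng):
    """Run every requested method on one pseudo-dataset; returns
    {tag: (spike_detected, null_detected, spike_estimate)}."""
    folds = scenario.folds
    cv_seed = int(rng.integers(0, 2**31 - 1))
    boot_seed = int(rng.integers(0, 2**31 - 1))
    test_idx = [spike, null]
    detected: dict[str, tuple[bool, bool, float]] = {}

    if "LMM" in methods:
        kin = compute_kinship(X_new)
        res = lmm_scan(y_star, X_new, kin, alpha=scenario.lmm_alpha,
                       m_tests=m, gene_subset=test_idx)
        detected["LMM"] = (bool(res[0].candidate), bool(res[1].candidate),
                           res[0].effect if res[0].effect is not None else np.nan)

    lasso_methods = [t for t in methods if t.startswith("LASSO")]
    if lasso_methods:
        curve = cv_curve(y_star, Xv, 1.0, folds=folds, seed=cv_seed)
        detected.update(_cd_family(y_star, Xv, curve, lasso_methods, "LASSO",
                                   test_idx, scenario, boot_seed))

    en_methods = [t for t in methods if t.startswith("EN")]
    if en_methods:
        _, curve = select_alpha(y_star, Xv, alpha_grid=scenario.alpha_grid,
                                folds=folds, seed=cv_seed)
        detected.update(_cd_family(y_star, Xv, curve, en_methods, "EN",
                                   test_idx, scenario, boot_seed + 1))

    rr_methods = [t for t in methods if t.startswith("RR")]
    if rr_methods:
        curve = cv_curve(y_star, Xv, 0.0, folds=folds, seed=cv_seed)
        specs, full_coefs = {}, {}
        for tag in rr_methods:
            rule = "min" if tag == "RR-Min" else "one_se"
            specs[tag] = select_tuning(curve, rule)
            full_coefs[tag], _ = fit_penalized(y_star, Xv, specs[tag])
        pvals = _rr_bootstrap_pvals(
            y_star, Xv, specs, test_idx, full_coefs,
            scenario.n_boot, scenario.boot_size,
            np.random.default_rng(boot_seed + 2),
        )
        for tag in rr_methods:
            p = pvals[tag]
            detected[tag] = (bool(p[0] <= 0.05), bool(p[1] <= 0.05),
                             float(full_coefs[tag][spike]))
    return detected


def _cd_family(y_star, Xv, curve, tags, base, test_idx, scenario, boot_seed):
    """Detections for the LASSO or EN family from one tuning curve."""
    out = {}
    if any(t in tags for t in (f"{base}-Min", f"{base}-Min-P")):
        spec_min = select_tuning(curve, "min")
        coef_min, _ = fit_penalized(y_star, Xv, spec_min)
        est = float(coef_min[test_idx[0]])
        nz = (coef_min[test_idx[0]] != 0.0, coef_min[test_idx[1]] != 0.0)
        if f"{base}-Min" in tags:
            out[f"{base}-Min"] = (*nz, est)
        if f"{base}-Min-P" in tags:
            p = _cd_bootstrap_pvals(
                y_star, Xv, spec_min, test_idx, coef_min,
                scenario.n_boot, scenario.boot_size,
                np.random.default_rng(boot_seed),
            )
            out[f"{base}-Min-P"] = (bool(nz[0] and p[0] <= 0.05),
                                    bool(nz[1] and p[1] <= 0.05), est)
    if f"{base}-1SE" in tags:
        spec_1se = select_tuning(curve, "one_se")
        coef_1se, _ = fit_penalized(y_star, Xv, spec_1se)
        out[f"{base}-1SE"] = (coef_1se[test_idx[0]] != 0.0,
                              coef_1se[test_idx[1]] != 0.0,
                              float(coef_1se[test_idx[0]]))
    return out


def benchmark_table(
    dataset: SyntheticDataset,
    scenarios: list[Scenario],
    trait: str | None = None,
) -> pd.DataFrame:
    """Run a list of scenarios against one dataset; returns the long-format
    (h, method, metric, value) table.  The neutral gene set is classified once
    from the base trait and shared across scenarios, as in the reference
    protocol."""
    if not scenarios:
        raise ValueError("scenarios must be non-empty")
    X = dataset.expression
    y = dataset.phenotypes[trait or dataset.phenotypes.columns[0]].to_numpy()
    first = scenarios[0]
    _, neutral = classify_genes(y, X, folds=first.folds, seed=first.seed,
                                alpha_grid=first.alpha_grid)
    rows = []
    for sc in scenarios:
        out = run_scenario(dataset, sc, neutral=neutral, trait=trait)
        for tag in sc.methods:
            rows.append({"h": sc.h, "method": tag, "metric": "power",
                         "value": out.power[tag], "n_replicates": sc.n_replicates})
            rows.append({"h": sc.h, "method": tag, "metric": "type1",
                         "value": out.type1[tag], "n_replicates": sc.n_replicates})
    return pd.DataFrame(rows)


def pivot_wide(table: pd.DataFrame, metric: str = "type1") -> pd.DataFrame:
    """Wide pivot (rows h, columns methods) of one metric."""
    sub = table[table["metric"] == metric]
    return sub.pivot(index="h", columns="method", values="value")
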