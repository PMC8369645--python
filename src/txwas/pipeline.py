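"""End-to-end empirical analysis: normalize -> standardize -> kinship ->
association by the configured methods -> candidate table and report.

The default method set is {LMM, LASSO-1SE, EN-1SE}: the three configurations
with the lowest type-I error in the simulation benchmark.  LMM candidates are
declared at the Bonferroni threshold alpha/m; 1SE-rule penalized candidates
are the genes with nonzero coefficients (no Wald filtering).  Min-rule and
ridge variants (with bootstrap Wald tests) are available but off by default.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lmm import AssociationResult, lmm_scan, results_to_frame
from .penalized import (
    BootstrapSpec,
    bootstrap_wald,
    cv_curve,
    fit_penalized,
    select_alpha,
    select_tuning,
)
from .preprocess import (
    ExpressionMatrix,
    compute_kinship,
    counts_to_expression,
    read_counts_tsv,
    standardize_vector,
)

logger = logging.getLogger("txwas")

__all__ = ["RunConfig", "run_association_suite", "associate_one",
           "write_report", "read_positions_bed"]

DEFAULT_METHODS = ("LMM", "LASSO-1SE", "EN-1SE")


@dataclass
class RunConfig:
    """Declarative configuration of one association run."""

    counts: str
    phenotypes: str
    outdir: str = "txwas_out"
    positions: str | None = None          # BED-like: gene_id, chrom, start, end
    traits: list[str] | None = None       # None = every phenotype column
    methods: tuple[str, ...] = DEFAULT_METHODS
    folds: int = 10
    alpha_grid: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 10))
    n_boot: int = 1000
    boot_size: int = 200
    bonferroni_alpha: float = 0.05
    log_counts: bool = True
    plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text())
        cfg = cls(**raw)
        for p in (cfg.counts, cfg.phenotypes, cfg.positions):
            if p is not None and not pathlib.Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def read_positions_bed(path) -> pd.DataFrame:
    """BED-like gene positions (gene_id, chrom, start, end; 0-based
    half-open), returned with 1-based inclusive coordinates for tables."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["gene_id", "chrom", "start", "end"])
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df.set_index("gene_id")


def associate_one(
    y: np.ndarray,
    X: ExpressionMatrix,
    method: str,
    kinship=None,
    folds: int = 10,
    alpha_grid=None,
    boot: BootstrapSpec | None = None,
    bonferroni_alpha: float = 0.05,
    seed: int = 0,
) -> list[AssociationResult]:
    """Run one method tag on one standardized trait; returns per-gene results
    with candidate flags set by the method's declaration rule."""
    y = standardize_vector(np.asarray(y, dtype=float))
    if method == "LMM":
        kin = kinship if kinship is not None else compute_kinship(X)
        return lmm_scan(y, X, kin, alpha=bonferroni_alpha)
    base, _, rule_tag = method.partition("-")
    wald = rule_tag.endswith("-P")
    rule = "min" if rule_tag.startswith("Min") else "one_se"
    if base == "LASSO":
        curve = cv_curve(y, X.values, 1.0, folds=folds, seed=seed)
    elif base == "EN":
        _, curve = select_alpha(y, X.values, alpha_grid=alpha_grid,
                                folds=folds, seed=seed)
    elif base == "RR":
        curve = cv_curve(y, X.values, 0.0, folds=folds, seed=seed)
        wald = True                      # ridge selects nothing; always tests
    else:
        raise ValueError(f"unknown method {method!r}")
    spec = select_tuning(curve, rule)
    coef, _ = fit_penalized(y, X.values, spec)
    logger.info("%s: alpha=%.2f lambda=%.4g nonzero=%d", method, spec.alpha,
                spec.lam, int(np.count_nonzero(coef)))
    if wald:
        test_set = (list(range(X.n_genes)) if base == "RR"
                    else list(np.nonzero(coef)[0]))
        if not test_set:
            return [AssociationResult(g, 0.0, None, None, None, method)
                    for g in X.gene_ids]
        boot = boot or BootstrapSpec(seed=seed)
        results = bootstrap_wald(y, X.values, spec, test_set, boot,
                                 method=method, gene_ids=X.gene_ids)
        tested = {r.gene_id: r for r in results}
        out = []
        for i, g in enumerate(X.gene_ids):
            if g in tested:
                r = tested[g]
                if base != "RR":
                    r.candidate = bool(r.candidate and coef[i] != 0.0)
                out.append(r)
            else:
                out.append(AssociationResult(g, float(coef[i]), None, None,
                                             None, method))
        return out
    return [
        AssociationResult(gene_id=g, effect=float(coef[i]), se=None, wald=None,
                          p_value=None, method=method,
                          candidate=bool(coef[i] != 0.0))
        for i, g in enumerate(X.gene_ids)
    ]


def run_association_suite(config: RunConfig):
    """Run every configured method on every requested trait.

    Returns (candidate_table, all_results) where the candidate table has one
    row per trait x gene x method, sorted by trait then |effect| descending.
    """
    counts, gene_ids, sample_ids = read_counts_tsv(config.counts)
    X, factors = counts_to_expression(counts, gene_ids, sample_ids,
                                      log=config.log_counts)
    pheno = pd.read_csv(config.phenotypes, index_col=0)
    pheno = pheno.loc[[s for s in X.sample_ids if s in pheno.index]]
    traits = config.traits or list(pheno.columns)
    missing = [t for t in traits if t not in pheno.columns]
    if missing:
        raise ValueError(
            f"trait(s) {missing} not in phenotype file; available: "
            f"{list(pheno.columns)}"
        )
    kin = compute_kinship(X) if "LMM" in config.methods else None
    positions = (read_positions_bed(config.positions)
                 if config.positions else None)
    boot = BootstrapSpec(n_boot=config.n_boot,
                         resample_size=min(config.boot_size, X.n_samples),
                         seed=config.seed)
    rows = []
    all_results = []
    for trait in traits:
        y = pheno[trait].to_numpy(dtype=float)
        for method in config.methods:
            res = associate_one(
                y, X, method, kinship=kin, folds=config.folds,
                alpha_grid=list(config.alpha_grid), boot=boot,
                bonferroni_alpha=config.bonferroni_alpha, seed=config.seed,
            )
            n_cand = sum(r.candidate for r in res)
            logger.info("trait=%s method=%s candidates=%d", trait, method, n_cand)
            for r in res:
                all_results.append((trait, r))
                if r.candidate:
                    row = {"trait": trait, "gene_id": r.gene_id,
                           "method": r.method, "effect": r.effect, "se": r.se}
                    if positions is not None and r.gene_id in positions.index:
                        row.update(positions.loc[r.gene_id].to_dict())
                    rows.append(row)
    cols = ["trait", "gene_id", "method", "effect", "se"]
    if positions is not None:
        cols += ["chrom", "start", "end"]
    table = pd.DataFrame(rows, columns=cols)
    if len(table):
        table = (table.assign(_abs=table["effect"].abs())
                 .sort_values(["trait", "_abs"], ascending=[True, False],
                              kind="mergesort")
                 .drop(columns="_abs")
                 .reset_index(drop=True))
    return table, all_results


def _sha256(path) -> str:
    return hashlib.sha256(pathlib.Path(path).read_bytes()).hexdigest()


def write_report(table: pd.DataFrame, all_results, config: RunConfig) -> dict:
    """Write candidate TSV, per-method result TSVs, and a JSON run manifest
    (config, seeds, package version, input checksums); optional plots."""
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    if all_results:
        res_frame = results_to_frame([r for _, r in all_results])
        res_frame.insert(0, "trait", [t for t, _ in all_results])
    else:
        res_frame = pd.DataFrame()
    res_frame.to_csv(outdir / "results.tsv", sep="\t", index=False)
    manifest = {
        "config": asdict(config),
        "version": __version__,
        "inputs": {
            "counts": _sha256(config.counts),
            "phenotypes": _sha256(config.phenotypes),
        },
        "n_candidates": int(len(table)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if config.plots and len(res_frame):
        _manhattan_plots(res_frame, config, outdir)
    return manifest


def _manhattan_plots(res_frame: pd.DataFrame, config: RunConfig, outdir) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for (trait, method), grp in res_frame.groupby(["trait", "method"]):
        fig, ax = plt.subplots(figsize=(8, 3))
        if grp["p_value"].notna().any():
            yv = -np.log10(grp["p_value"].astype(float).clip(lower=1e-300))
            ax.set_ylabel("-log10 p")
        else:
            yv = grp["effect"].astype(float)
            ax.set_ylabel("effect (SD units)")
        ax.scatter(range(len(grp)), yv, s=4)
        ax.set_title(f"{trait} - {method}")
        ax.set_xlabel("gene index")
        fig.tight_layout()
        fig.savefig(outdir / f"manhattan_{trait}_{method}.png", dpi=100)
        plt.close(fig)
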