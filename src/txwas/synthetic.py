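"""Synthetic bulk RNA-seq expression and quantitative traits.

The generator emulates the statistical structure the association models
assume: a few hundred samples, a couple of thousand unit-variance genes
organized into co-expression modules (a Gaussian latent-factor layer, with an
optional negative-binomial count layer on top), and quantitative traits built
as

    y = sum_j b_j x_j + a + e,

where a handful of causal genes contribute sparse fixed effects ``b_j`` (in
phenotype-SD units), ``a`` is a polygenic effect drawn against the kinship of
the generated expression itself, and ``e`` is independent noise filling the
variance budget to one.  The default trait is rescaled to mean 83.68 and
SD 11.66 (CV 13.93%), matching the body-composition trait scale the pipeline
is aimed at.

All randomness flows from one integer seed through named substreams
(`numpy.random.SeedSequence` spawn keys), so expression, phenotypes and
shuffles are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .preprocess import (
    ExpressionMatrix,
    compute_kinship,
    counts_to_expression,
    standardize,
    standardize_vector,
    write_counts_tsv,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_expression",
           "generate_phenotype", "generate_study"]

# substream labels -> spawn keys, so each consumer gets an independent stream
_STREAMS = {"expression": 0, "counts": 1, "polygenic": 2, "noise": 3,
            "traits": 4, "shuffle": 5}


def substream(seed: int, name: str, index: int = 0) -> np.random.Generator:
    """Independent, reproducible child stream of the master seed."""
    key = (_STREAMS[name], index) if index else (_STREAMS[name],)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    ``causal_genes`` maps gene indices to fixed-effect sizes in phenotype-SD
    units on a unit-variance gene; a gene with effect b contributes b**2 of
    the (unit) phenotypic variance.  ``polygenic_h2`` is the variance
    proportion of the polygenic term; the remaining variance is i.i.d. noise.
    """

    n_samples: int = 400
    n_genes: int = 2000
    n_modules: int = 20
    module_size: int = 50
    module_loading: float = 0.7
    causal_genes: list[tuple[int, float]] = field(
        default_factory=lambda: [(i, np.sqrt(0.02)) for i in range(5)]
    )
    polygenic_h2: float = 0.3
    noise_model: str = "gaussian"  # or "negative_binomial"
    nb_dispersion: float = 0.1
    n_traits: int = 1
    trait_corr: float | None = None  # correlation of extra traits with trait 1
    trait_mean: float = 83.68
    trait_sd: float = 11.66
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 3:
            raise ValueError("at least 3 samples required")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.module_loading <= 1.0:
            raise ValueError("module_loading must lie in [0, 1]")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("n_modules * module_size exceeds n_genes")
        if not 0.0 <= self.polygenic_h2 < 1.0:
            raise ValueError("polygenic_h2 must lie in [0, 1)")
        idx = [i for i, _ in self.causal_genes]
        if len(set(idx)) != len(idx):
            raise ValueError("causal gene indices must be distinct")
        if any(i < 0 or i >= self.n_genes for i in idx):
            raise ValueError("causal gene index out of range")
        budget = self.polygenic_h2 + sum(b * b for _, b in self.causal_genes)
        if budget >= 1.0:
            raise ValueError(
                f"variance budget {budget:.3f} (polygenic + causal) must be < 1"
            )
        if self.noise_model not in ("gaussian", "negative_binomial"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_traits < 1:
            raise ValueError("n_traits must be >= 1")


@dataclass
class SyntheticDataset:
    """Generated study bundle: counts (NB model only), standardized
    expression, trait table, and the ground-truth record."""

    expression: ExpressionMatrix
    phenotypes: pd.DataFrame
    counts: np.ndarray | None
    truth: dict

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples


def _latent_expression(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Gaussian factor layer: module genes load on a shared per-sample factor,
    scaled so every gene has unit variance; off-module genes are pure noise."""
    n, m = config.n_samples, config.n_genes
    rho = config.module_loading
    Z = rng.standard_normal((n, m))
    if config.n_modules > 0 and rho > 0:
        factors = rng.standard_normal((n, config.n_modules))
        resid = np.sqrt(1.0 - rho * rho)
        for g in range(config.n_modules):
            lo = g * config.module_size
            hi = lo + config.module_size
            Z[:, lo:hi] = rho * factors[:, [g]] + resid * Z[:, lo:hi]
    return Z


def generate_expression(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the expression part of a study (no phenotypes yet)."""
    config.validate()
    rng = substream(config.seed, "expression")
    Z = _latent_expression(config, rng)
    gene_ids = [f"gene_{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"sample_{j:04d}" for j in range(config.n_samples)]
    module_of = {
        gene_ids[i]: (i // config.module_size if i < config.n_modules * config.module_size else -1)
        for i in range(config.n_genes)
    }
    counts = None
    if config.noise_model == "negative_binomial":
        crng = substream(config.seed, "counts")
        # exp link around a gene-specific baseline; gamma-Poisson mixture
        log_base = crng.normal(np.log(100.0), 1.0, size=config.n_genes)
        mu = np.exp(log_base[None, :] + 0.3 * Z)  # samples x genes
        shape = 1.0 / config.nb_dispersion
        lam = crng.gamma(shape, mu * config.nb_dispersion)
        counts = crng.poisson(lam).T.astype(np.int64)  # genes x samples
        expr, _ = counts_to_expression(counts, gene_ids, sample_ids)
    else:
        mat = ExpressionMatrix(values=Z, gene_ids=gene_ids, sample_ids=sample_ids)
        expr = standardize(mat)
    truth = {
        "seed": config.seed,
        "module_of": module_of,
        "causal_genes": [],
        "config": {k: v for k, v in asdict(config).items()},
    }
    return SyntheticDataset(expression=expr, phenotypes=pd.DataFrame(index=sample_ids),
                            counts=counts, truth=truth)


def generate_phenotype(
    dataset: SyntheticDataset,
    causal_genes: list[tuple[int, float]],
    polygenic_h2: float,
    seed: int,
    trait_index: int = 0,
) -> np.ndarray:
    """Draw one unit-scale trait: sparse causal effects + polygenic + noise.

    The polygenic term is multivariate normal with covariance
    ``polygenic_h2 * K`` where K is the kinship of the generated expression,
    so variance-component recovery by the LMM is well-posed.  Raises if the
    total variance budget reaches 1.
    """
    X = dataset.expression
    if not X.standardized:
        raise ValueError("dataset expression must be standardized")
    budget = polygenic_h2 + sum(b * b for _, b in causal_genes)
    if budget >= 1.0:
        raise ValueError(f"variance budget {budget:.3f} must be < 1")
    n = X.n_samples
    y = np.zeros(n)
    for i, b in causal_genes:
        y += b * X.values[:, i]
    realized = {"causal": sum(b * b for _, b in causal_genes)}
    if polygenic_h2 > 0:
        kin = compute_kinship(X)
        rng = substream(seed, "polygenic", trait_index)
        z = rng.standard_normal(n)
        a = kin.eigenvectors @ (np.sqrt(polygenic_h2 * kin.eigenvalues) * z)
        y += a
        realized["polygenic"] = polygenic_h2
    else:
        realized["polygenic"] = 0.0
    rng_e = substream(seed, "noise", trait_index)
    sigma_e = np.sqrt(1.0 - budget)
    y += sigma_e * rng_e.standard_normal(n)
    realized["noise"] = 1.0 - budget
    dataset.truth.setdefault("traits", {})[f"trait_{trait_index + 1}"] = {
        "causal_genes": [(int(i), float(b)) for i, b in causal_genes],
        "variance_decomposition": realized,
    }
    return y


def generate_study(config: SyntheticConfig | None = None, **overrides) -> SyntheticDataset:
    """Full study bundle: expression (+ counts under the NB model) and >= 1
    trait on the configured mean/SD scale, with a complete truth record."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    config.validate()
    ds = generate_expression(config)
    traits = {}
    y1 = generate_phenotype(ds, config.causal_genes, config.polygenic_h2,
                            config.seed, trait_index=0)
    y1_std = standardize_vector(y1)
    traits["trait_1"] = config.trait_mean + config.trait_sd * y1_std
    trng = substream(config.seed, "traits")
    for t in range(1, config.n_traits):
        if config.trait_corr is not None:
            rho = config.trait_corr
            raw = rho * y1_std + np.sqrt(1 - rho * rho) * trng.standard_normal(ds.n_samples)
        else:
            raw = trng.standard_normal(ds.n_samples)
        traits[f"trait_{t + 1}"] = config.trait_mean + config.trait_sd * standardize_vector(raw)
        ds.truth.setdefault("traits", {})[f"trait_{t + 1}"] = {
            "causal_genes": [],
            "corr_with_trait_1": config.trait_corr,
        }
    ds.truth["causal_genes"] = [(int(i), float(b)) for i, b in config.causal_genes]
    ds.phenotypes = pd.DataFrame(traits, index=ds.expression.sample_ids)
    ds.phenotypes.index.name = "sample_id"
    return ds


def write_study(ds: SyntheticDataset, outdir, write_mtx: bool = False) -> None:
    """Write counts TSV (and optional MatrixMarket), phenotype CSV, truth JSON."""
    import pathlib
    import scipy.io
    import scipy.sparse

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = ds.expression
    if ds.counts is not None:
        write_counts_tsv(ds.counts, expr.gene_ids, expr.sample_ids, outdir / "counts.tsv")
        if write_mtx:
            scipy.io.mmwrite(str(outdir / "counts.mtx"), scipy.sparse.csr_matrix(ds.counts))
            (outdir / "counts.mtx.rows").write_text("\n".join(expr.gene_ids) + "\n")
            (outdir / "counts.mtx.cols").write_text("\n".join(expr.sample_ids) + "\n")
    # standardized expression is always written (gene x sample, like counts)
    pd.DataFrame(expr.values.T, index=expr.gene_ids, columns=expr.sample_ids).to_csv(
        outdir / "expression.tsv", sep="\t", index_label="gene_id"
    )
    ds.phenotypes.to_csv(outdir / "phenotypes.csv")
    truth = dict(ds.truth)
    truth["module_of"] = {k: int(v) for k, v in truth["module_of"].items()}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
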