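"""Count normalization, standardization, and the expression-derived kinship matrix.

The association models downstream treat per-gene expression vectors the way a
GWAS treats marker genotypes: every gene is scaled to zero mean and unit
variance, and an n x n sample-similarity ("kinship") matrix is built from the
full standardized expression matrix,

    K = (1/d) * sum_i X_i X_i',

where ``X_i`` is the i-th standardized gene-expression vector across samples
and ``d`` is the average diagonal of the unnormalized sum, so that
``mean(diag(K)) = 1`` and ``trace(K) = n``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.linalg
import scipy.sparse

logger = logging.getLogger("txwas")

__all__ = [
    "ExpressionMatrix",
    "KinshipMatrix",
    "size_factors",
    "normalize_counts",
    "log_transform",
    "standardize",
    "standardize_vector",
    "compute_kinship",
    "read_counts_tsv",
    "read_counts_mtx",
    "write_counts_tsv",
]


@dataclass
class ExpressionMatrix:
    """Samples x genes expression values with identifiers.

    ``values[j, i]`` is the expression of gene ``gene_ids[i]`` in sample
    ``sample_ids[j]``.  ``standardized`` records whether every column has been
    scaled to mean 0 and sample SD 1 (n-1 denominator).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x genes)")
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.gene_ids) != m:
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples / {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class KinshipMatrix:
    """Expression kinship K with its (lazily computed) eigendecomposition.

    ``d`` is the average diagonal of ``sum_i X_i X_i'`` used to normalize K so
    that its diagonal averages to one.  Eigenvalues slightly below zero (down
    to -1e-8) are clipped to zero; anything lower raises, because the kinship
    of a real expression matrix is positive semi-definite by construction.
    """

    K: np.ndarray
    d: float
    _eigenvalues: np.ndarray | None = field(default=None, repr=False)
    _eigenvectors: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n):
            raise ValueError("K must be square")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric to 1e-10")
        if abs(float(np.mean(np.diag(self.K))) - 1.0) > 1e-10:
            raise ValueError("mean diagonal of K must equal 1")
        if self.d <= 0:
            raise ValueError("d must be positive")

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def _ensure_eig(self) -> None:
        if self._eigenvalues is None:
            s, U = scipy.linalg.eigh(self.K)
            if s.min() < -1e-8:
                raise ValueError(
                    f"kinship matrix has eigenvalue {s.min():.3e} below -1e-8; "
                    "input is not a valid expression kinship"
                )
            self._eigenvalues = np.clip(s, 0.0, None)
            self._eigenvectors = U

    @property
    def eigenvalues(self) -> np.ndarray:
        self._ensure_eig()
        return self._eigenvalues

    @property
    def eigenvectors(self) -> np.ndarray:
        self._ensure_eig()
        return self._eigenvectors


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample size factors for a genes x samples count matrix.

    The reference for each gene is its geometric mean across samples, computed
    only over genes with strictly positive counts in every sample; a sample's
    factor is the median across those genes of count / geometric mean.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (genes x samples)")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    all_positive = np.all(counts > 0, axis=1)
    if not np.any(all_positive):
        raise ValueError(
            "no gene has all-positive counts; size factors are undefined"
        )
    ref = counts[all_positive]
    log_geo_mean = np.mean(np.log(ref), axis=1)
    log_ratios = np.log(ref) - log_geo_mean[:, None]
    return np.exp(np.median(log_ratios, axis=0))


def normalize_counts(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Divide each sample's counts by its size factor; returns (normalized, factors)."""
    factors = size_factors(counts)
    return np.asarray(counts, dtype=float) / factors[None, :], factors


def log_transform(normalized: np.ndarray) -> np.ndarray:
    """log2(normalized count + 1), the default variance-stabilizing step."""
    return np.log2(np.asarray(normalized, dtype=float) + 1.0)


def standardize_vector(y: np.ndarray) -> np.ndarray:
    """Scale a vector to mean 0 and unit sample SD (n-1 denominator)."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (y - y.mean()) / sd


def standardize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Column-standardize an expression matrix, dropping constant genes.

    Each retained column ends with mean 0 and sample SD 1 (n-1 denominator).
    Constant columns carry no association information and are removed with a
    logged warning rather than producing NaNs.
    """
    X = matrix.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to standardize")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
        logger.warning(
            "dropping %d constant gene(s) before standardization: %s%s",
            n_dropped,
            ", ".join(dropped[:5]),
            "..." if n_dropped > 5 else "",
        )
    Xk = X[:, keep]
    Z = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0, ddof=1)
    return ExpressionMatrix(
        values=Z,
        gene_ids=[g for g, k in zip(matrix.gene_ids, keep) if k],
        sample_ids=list(matrix.sample_ids),
        standardized=True,
    )


def compute_kinship(X: ExpressionMatrix) -> KinshipMatrix:
    """Expression kinship K = (1/d) sum_i X_i X_i' from a standardized matrix.

    ``d`` is the mean diagonal of the raw accumulation, which forces
    ``trace(K) = n``.  Requires the input to be flagged standardized, since an
    unscaled matrix would let high-variance genes dominate the similarity.
    """
    if not X.standardized:
        raise ValueError("compute_kinship requires a standardized ExpressionMatrix")
    V = X.values
    S = V @ V.T
    d = float(np.mean(np.diag(S)))
    if d <= 0:
        raise ValueError("degenerate expression matrix: zero diagonal")
    return KinshipMatrix(K=S / d, d=d)


def write_kinship(kin: KinshipMatrix, path, eigen_sidecar: bool = True) -> None:
    """Write K as a TSV; optionally an .npz sidecar caching d and the
    eigendecomposition so downstream fits skip the O(n^3) step."""
    import pathlib

    path = pathlib.Path(path)
    with open(path, "w") as fh:
        fh.write(f"# d={kin.d!r}\n")           # d is not recoverable from K
        np.savetxt(fh, kin.K, delimiter="\t")
    if eigen_sidecar:
        np.savez(path.with_suffix(path.suffix + ".npz"),
                 eigenvalues=kin.eigenvalues, eigenvectors=kin.eigenvectors)


def read_kinship(path) -> KinshipMatrix:
    """Read a kinship TSV written by :func:`write_kinship`, restoring the
    cached eigendecomposition from the sidecar when present."""
    import pathlib

    path = pathlib.Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# d="):
            raise ValueError("kinship TSV missing its '# d=' header line")
        d = float(header.split("=", 1)[1])
        K = np.loadtxt(fh, delimiter="\t")
    kin = KinshipMatrix(K=K, d=d)
    sidecar = path.with_suffix(path.suffix + ".npz")
    if sidecar.exists():
        cache = np.load(sidecar)
        kin._eigenvalues = cache["eigenvalues"]
        kin._eigenvectors = cache["eigenvectors"]
    return kin


# ---------------------------------------------------------------------------
# I/O glue: counts as genes x samples TSV or MatrixMarket

def write_counts_tsv(counts: np.ndarray, gene_ids, sample_ids, path) -> None:
    df = pd.DataFrame(counts, index=list(gene_ids), columns=list(sample_ids))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str))


def read_counts_mtx(path, gene_index_path, sample_index_path):
    """Read MatrixMarket counts with row (gene) and column (sample) id sidecars."""
    mat = scipy.io.mmread(path)
    counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    genes = [line.strip() for line in open(gene_index_path) if line.strip()]
    samples = [line.strip() for line in open(sample_index_path) if line.strip()]
    if counts.shape != (len(genes), len(samples)):
        raise ValueError("MatrixMarket shape inconsistent with index sidecars")
    return counts, genes, samples


def counts_to_expression(
    counts: np.ndarray,
    gene_ids,
    sample_ids,
    log: bool = True,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Full preprocessing path: size-factor normalize, optionally log2(x+1),
    transpose to samples x genes, and standardize.  Returns the standardized
    matrix and the size factors used."""
    normalized, factors = normalize_counts(counts)
    vals = log_transform(normalized) if log else normalized
    mat = ExpressionMatrix(
        values=vals.T, gene_ids=list(gene_ids), sample_ids=list(sample_ids)
    )
    return standardize(mat), factors
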