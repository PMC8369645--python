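import numpy as np
import pytest

from txwas import SyntheticConfig, generate_study
from txwas.preprocess import ExpressionMatrix, standardize


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale synthetic study shared by read-only tests."""
    cfg = SyntheticConfig(
        n_samples=120, n_genes=200, n_modules=4, module_size=25,
        causal_genes=[(0, np.sqrt(0.10))], polygenic_h2=0.2, seed=7,
    )
    return generate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_std_matrix(n, m, seed=0):
    """Standardized ExpressionMatrix of i.i.d. noise."""
    raw = np.random.default_rng(seed).standard_normal((n, m))
    mat = ExpressionMatrix(
        values=raw,
        gene_ids=[f"g{i}" for i in range(m)],
        sample_ids=[f"s{j}" for j in range(n)],
    )
    return standardize(mat)
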