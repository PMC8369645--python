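import numpy as np
import pytest

from txwas import SyntheticConfig, generate_expression, generate_phenotype, generate_study
from txwas.lmm import reml_fit
from txwas.preprocess import compute_kinship, standardize_vector


def test_same_seed_bit_identical():
    cfg = SyntheticConfig(n_samples=50, n_genes=80, n_modules=2, module_size=20, seed=3)
    a = generate_study(cfg)
    b = generate_study(SyntheticConfig(n_samples=50, n_genes=80, n_modules=2,
                                       module_size=20, seed=3))
    assert np.array_equal(a.expression.values, b.expression.values)
    assert a.phenotypes.equals(b.phenotypes)


def test_no_modules_means_near_independence():
    cfg = SyntheticConfig(n_samples=400, n_genes=60, n_modules=0, module_loading=0.0,
                          causal_genes=[], polygenic_h2=0.0, seed=5)
    ds = generate_expression(cfg)
    R = np.corrcoef(ds.expression.values.T)
    off = np.abs(R[np.triu_indices_from(R, k=1)])
    assert off.mean() <= 3 / np.sqrt(400)


def test_module_structure_raises_within_module_correlation():
    cfg = SyntheticConfig(n_samples=400, n_genes=200, n_modules=2, module_size=50,
                          module_loading=0.9, causal_genes=[], polygenic_h2=0.0, seed=6)
    ds = generate_expression(cfg)
    V = ds.expression.values
    R = np.abs(np.corrcoef(V.T))
    within = np.concatenate([
        R[:50, :50][np.triu_indices(50, k=1)],
        R[50:100, 50:100][np.triu_indices(50, k=1)],
    ])
    between = R[:50, 50:100].ravel()
    assert within.mean() > between.mean()
    # loading 0.9 -> within-module correlation ~0.81
    assert within.mean() > 0.5


def test_expression_columns_standardized():
    ds = generate_expression(SyntheticConfig(n_samples=60, n_genes=40, n_modules=1,
                                             module_size=10, seed=8))
    V = ds.expression.values
    assert np.all(np.abs(V.mean(axis=0)) < 1e-8)
    assert np.allclose(V.std(axis=0, ddof=1), 1.0, atol=1e-8)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="exceeds n_genes"):
        SyntheticConfig(n_genes=50, n_modules=3, module_size=20).validate()
    with pytest.raises(ValueError, match="module_loading"):
        SyntheticConfig(module_loading=1.5).validate()
    with pytest.raises(ValueError, match="budget"):
        SyntheticConfig(causal_genes=[(0, 0.9)], polygenic_h2=0.3).validate()
    with pytest.raises(ValueError, match="3 samples"):
        SyntheticConfig(n_samples=1).validate()
    with pytest.raises(ValueError, match="distinct"):
        SyntheticConfig(causal_genes=[(0, 0.1), (0, 0.2)]).validate()


class TestPhenotype:
    def test_pure_noise_uncorrelated_with_genes(self):
        cfg = SyntheticConfig(n_samples=200, n_genes=100, n_modules=0,
                              causal_genes=[], polygenic_h2=0.0, seed=9)
        ds = generate_expression(cfg)
        y = generate_phenotype(ds, [], 0.0, seed=9)
        r = np.array([np.corrcoef(ds.expression.values[:, i], y)[0, 1]
                      for i in range(100)])
        assert abs(r.mean()) <= 3 / np.sqrt(200 * 100) * 10  # mean of m noisy r's

    def test_single_causal_gene_r2_matches_h(self):
        h = 0.20
        cfg = SyntheticConfig(n_samples=400, n_genes=50, n_modules=0,
                              causal_genes=[], polygenic_h2=0.0, seed=10)
        ds = generate_expression(cfg)
        y = generate_phenotype(ds, [(3, np.sqrt(h))], 0.0, seed=10)
        r2 = np.corrcoef(ds.expression.values[:, 3], y)[0, 1] ** 2
        assert r2 == pytest.approx(h, abs=0.06)

    def test_causal_r2_unbiased_over_replicates(self):
        # realized R^2 should match the requested variance proportion within
        # 3 Monte-Carlo SEs over 50 seeded replicates
        h = 0.20
        r2s = []
        for seed in range(50):
            cfg = SyntheticConfig(n_samples=200, n_genes=20, n_modules=0,
                                  causal_genes=[], polygenic_h2=0.0, seed=seed)
            ds = generate_expression(cfg)
            y = generate_phenotype(ds, [(0, np.sqrt(h))], 0.0, seed=seed)
            r2s.append(np.corrcoef(ds.expression.values[:, 0], y)[0, 1] ** 2)
        r2s = np.array(r2s)
        sem = r2s.std(ddof=1) / np.sqrt(len(r2s))
        # E[r^2] has a small positive O(1/n) bias; allow for it
        assert abs(r2s.mean() - h) <= 3 * sem + (1 - h) ** 2 / 200

    def test_polygenic_variance_recovered_by_reml(self):
        cfg = SyntheticConfig(n_samples=400, n_genes=400, n_modules=8,
                              module_size=50, causal_genes=[],
                              polygenic_h2=0.5, seed=11)
        ds = generate_expression(cfg)
        y = generate_phenotype(ds, [], 0.5, seed=11)
        kin = compute_kinship(ds.expression)
        fit = reml_fit(standardize_vector(y), None, kin)
        assert fit.heritability == pytest.approx(0.5, abs=0.15)

    def test_budget_over_one_rejected(self):
        ds = generate_expression(SyntheticConfig(n_samples=50, n_genes=10,
                                                 n_modules=0, causal_genes=[],
                                                 polygenic_h2=0.0, seed=1))
        with pytest.raises(ValueError, match="budget"):
            generate_phenotype(ds, [(0, 0.8)], 0.5, seed=1)


class TestStudy:
    def test_default_trait_cv(self):
        ds = generate_study(SyntheticConfig(n_samples=400, n_genes=100, n_modules=0,
                                            causal_genes=[], polygenic_h2=0.0, seed=12))
        y = ds.phenotypes["trait_1"]
        cv = 100 * y.std(ddof=1) / y.mean()
        assert cv == pytest.approx(13.93, abs=1.5)

    def test_two_traits_with_prescribed_correlation(self):
        ds = generate_study(SyntheticConfig(n_samples=398, n_genes=50, n_modules=0,
                                            causal_genes=[], polygenic_h2=0.0,
                                            n_traits=2, trait_corr=0.49, seed=13))
        r = np.corrcoef(ds.phenotypes["trait_1"], ds.phenotypes["trait_2"])[0, 1]
        assert r == pytest.approx(0.49, abs=0.09)

    def test_truth_record_complete(self, small_study):
        truth = small_study.truth
        assert truth["seed"] == 7
        assert truth["causal_genes"] == [(0, pytest.approx(np.sqrt(0.10)))]
        assert "trait_1" in truth["traits"]
        assert "variance_decomposition" in truth["traits"]["trait_1"]

    def test_negative_binomial_counts_layer(self):
        cfg = SyntheticConfig(n_samples=40, n_genes=60, n_modules=1, module_size=20,
                              causal_genes=[], polygenic_h2=0.0,
                              noise_model="negative_binomial", seed=14)
        ds = generate_study(cfg)
        assert ds.counts is not None
        assert ds.counts.dtype.kind == "i"
        assert np.all(ds.counts >= 0)
        assert ds.counts.shape[1] == 40  # genes x samples
        V = ds.expression.values
        assert np.allclose(V.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_write_study_round_trip(self, tmp_path):
        from txwas.synthetic import write_study
        from txwas.preprocess import read_counts_tsv

        cfg = SyntheticConfig(n_samples=20, n_genes=30, n_modules=0, causal_genes=[],
                              polygenic_h2=0.0, noise_model="negative_binomial", seed=15)
        ds = generate_study(cfg)
        write_study(ds, tmp_path)
        counts, genes, samples = read_counts_tsv(tmp_path / "counts.tsv")
        assert np.array_equal(counts, ds.counts)
        assert (tmp_path / "phenotypes.csv").exists()
        assert (tmp_path / "truth.json").exists()
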