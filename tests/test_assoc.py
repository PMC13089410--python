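import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lofburden.assoc import (
    BurdenScan,
    compute_kinship,
    compute_pcs,
    emmax_scan,
    glm_scan,
    int_transform,
    prep_expression,
    reml_fit,
)
from lofburden.assoc import _RotatedNull, _check_psd
from lofburden.simulate import SimulationConfig, simulate_population


def gls_oracle(y, x, K, C, delta):
    """Explicit-inverse GLS with per-marker residual scale (the slow way)."""
    n = len(y)
    H = K + delta * np.eye(n)
    Hi = np.linalg.inv(H)
    X = np.column_stack([C, x])
    XtHiX = X.T @ Hi @ X
    beta = np.linalg.solve(XtHiX, X.T @ Hi @ y)
    r = y - X @ beta
    df = n - X.shape[1]
    s2 = (r @ Hi @ r) / df
    cov = s2 * np.linalg.inv(XtHiX)
    se = np.sqrt(cov[-1, -1])
    t = beta[-1] / se
    return beta[-1], se, 2 * stats.t.sf(abs(t), df)


class TestPreprocessing:
    def test_log2_with_min_fill(self):
        raw = pd.DataFrame({"g": [0.0, 2.0, 8.0]}, index=list("abc"))
        out = prep_expression(raw)
        assert out["g"].tolist() == [1.0, 1.0, 3.0]

    def test_all_positive_plain_log2(self):
        raw = pd.DataFrame({"g": [1.0, 4.0]}, index=list("ab"))
        assert prep_expression(raw)["g"].tolist() == [0.0, 2.0]

    def test_all_zero_gene_floored_with_warning(self):
        raw = pd.DataFrame({"g": [0.0, 0.0]}, index=list("ab"))
        with pytest.warns(UserWarning, match="all-zero"):
            out = prep_expression(raw, floor=0.0)
        assert out["g"].tolist() == [0.0, 0.0]

    def test_rank_preservation_on_generated_matrix(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.gamma(2.0, 5.0, size=(40, 5)))
        out = prep_expression(raw)
        for c in raw.columns:
            assert (
                stats.spearmanr(raw[c], out[c]).statistic == pytest.approx(1.0)
            )


class TestIntTransform:
    def test_three_point_quantile_oracle(self):
        got = int_transform(np.array([5.0, 1.0, 9.0]))
        expected = stats.norm.ppf([2 / 4, 1 / 4, 3 / 4])
        np.testing.assert_allclose(got, expected, atol=1e-12)
        assert got[1] == pytest.approx(-0.67449, abs=1e-4)

    def test_ties_share_transformed_value(self):
        got = int_transform(np.array([3.0, 3.0, 1.0, 7.0]))
        assert got[0] == got[1]

    def test_monotone_invariance(self):
        y = np.array([0.3, 2.0, 1.1, 5.0, 4.2])
        np.testing.assert_allclose(int_transform(y), int_transform(np.exp(y)))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            int_transform(np.ones(5))


class TestKinshipAndPcs:
    def test_identical_accessions_have_equal_rows(self):
        G = pd.DataFrame([[0, 2, 2], [0, 2, 2], [2, 0, 0]], index=list("abc"))
        K = compute_kinship(G)
        np.testing.assert_allclose(K.loc["a"], K.loc["b"])
        assert K.loc["a", "b"] == pytest.approx(K.loc["a", "a"])

    def test_row_sums_near_zero(self):
        rng = np.random.default_rng(1)
        G = pd.DataFrame(2 * rng.integers(0, 2, (30, 200)))
        K = compute_kinship(G)
        assert np.abs(K.sum(axis=1)).max() < 1e-8 * 200

    def test_monomorphic_only_rejected(self):
        with pytest.raises(ValueError, match="polymorphic"):
            compute_kinship(pd.DataFrame([[2, 2], [2, 2]]))

    def test_structured_population_kinship_and_pc1(self):
        cfg = SimulationConfig(n_accessions=200, n_snps=1000, n_subpops=2,
                               fst_like_divergence=0.3, seed=3)
        G, labels, K = simulate_population(cfg)
        a = labels[labels == 0].index
        b = labels[labels == 1].index
        within = (K.loc[a, a].to_numpy().mean() + K.loc[b, b].to_numpy().mean()) / 2
        between = K.loc[a, b].to_numpy().mean()
        assert within > between
        pcs = compute_pcs(G, k=5)
        assert (
            abs(pcs.loc[a, "PC1"].mean() - pcs.loc[b, "PC1"].mean())
            > 2 * (pcs.loc[a, "PC1"].std() + pcs.loc[b, "PC1"].std())
        )

    def test_pcs_orthonormal(self):
        rng = np.random.default_rng(2)
        G = pd.DataFrame(2 * rng.integers(0, 2, (40, 300)))
        P = compute_pcs(G, k=5).to_numpy()
        np.testing.assert_allclose(P.T @ P, np.eye(5), atol=1e-8)

    def test_k_too_large_rejected(self):
        G = pd.DataFrame(2 * np.eye(4))
        with pytest.raises(ValueError, match="smaller"):
            compute_pcs(G, k=4)


class TestReml:
    def test_pure_noise_gives_small_h2(self):
        """Null limit: with an informative kinship (several diverged groups,
        so the spectrum is spread), pure-noise phenotypes yield h2 near 0."""
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(n_accessions=300, n_snps=1000, n_subpops=8,
                                   fst_like_divergence=0.3, seed=seed)
            G, _, K = simulate_population(cfg)
            y = np.random.default_rng(seed + 500).standard_normal(300)
            vc = reml_fit(y, np.ones((300, 1)), K.to_numpy())
            hits += vc.h2 < 0.1
        assert hits >= 19  # 95% of seeds

    def test_h2_recovery_moderate(self):
        est = []
        for seed in range(10):
            cfg = SimulationConfig(n_accessions=300, n_snps=400, seed=seed, h2=0.5)
            G, _, K = simulate_population(cfg)
            n = 300
            Kn = K.to_numpy()
            Ks = Kn * (n / np.trace(Kn))
            L = np.linalg.cholesky(Ks + 1e-8 * np.eye(n))
            rng = np.random.default_rng(seed + 900)
            y = np.sqrt(0.5) * (L @ rng.standard_normal(n)) + np.sqrt(0.5) * rng.standard_normal(n)
            est.append(reml_fit(y, np.ones((n, 1)), Kn).h2)
        assert abs(np.mean(est) - 0.5) < 0.1

    def test_optimum_beats_fine_grid(self):
        cfg = SimulationConfig(n_accessions=100, n_snps=300, seed=5, h2=0.4)
        G, _, K = simulate_population(cfg)
        rng = np.random.default_rng(17)
        y = rng.standard_normal(100)
        C = np.ones((100, 1))
        vc = reml_fit(y, C, K.to_numpy())
        lam, U = _check_psd(K.to_numpy())
        rot = _RotatedNull(y, C, lam, U)
        grid = np.linspace(-5, 5, 1000)
        grid_best = max(rot.reml_loglik(g)[0] for g in grid)
        assert vc.reml_loglik >= grid_best - 1e-6


class TestEmmaxScan:
    def test_matches_explicit_gls_oracle(self):
        rng = np.random.default_rng(0)
        for rep in range(10):
            n = 30
            G = pd.DataFrame(2 * rng.integers(0, 2, (n, 80)))
            K = compute_kinship(G).to_numpy()
            y = rng.standard_normal(n)
            X = rng.integers(0, 2, (n, 4)).astype(float)
            res = emmax_scan(y, X, K)
            delta = res.attrs["variance_components"]["delta"]
            for j in range(4):
                b, se, p = gls_oracle(y, X[:, j], K, np.ones((n, 1)), delta)
                assert res.iloc[j].beta == pytest.approx(b, rel=1e-8)
                assert res.iloc[j].p_value == pytest.approx(p, rel=1e-8)

    def test_identity_kinship_equals_ols(self):
        rng = np.random.default_rng(3)
        n = 50
        y = rng.standard_normal(n)
        X = rng.integers(0, 2, (n, 6)).astype(float)
        res = emmax_scan(y, X, np.eye(n))
        import statsmodels.api as sm

        for j in range(6):
            fit = sm.OLS(y, sm.add_constant(X[:, j])).fit()
            assert res.iloc[j].p_value == pytest.approx(fit.pvalues[1], abs=1e-6)

    def test_constant_marker_gives_nan_p(self):
        rng = np.random.default_rng(4)
        n = 30
        y = rng.standard_normal(n)
        X = np.column_stack([np.zeros(n), rng.integers(0, 2, n)])
        with pytest.warns(UserWarning, match="constant"):
            res = emmax_scan(y, X, np.eye(n))
        assert np.isnan(res.iloc[0].p_value)
        assert np.isfinite(res.iloc[1].p_value)

    def test_scale_invariance_of_p_values(self):
        rng = np.random.default_rng(5)
        cfg = SimulationConfig(n_accessions=80, n_snps=200, seed=6)
        G, _, K = simulate_population(cfg)
        y = rng.standard_normal(80)
        X = rng.integers(0, 2, (80, 5)).astype(float)
        p1 = emmax_scan(y, X, K.to_numpy())["p_value"]
        p2 = emmax_scan(7.3 * y, X, K.to_numpy())["p_value"]
        np.testing.assert_allclose(p1, p2, rtol=1e-6)

    def test_null_phenotype_p_values_uniform(self):
        cfg = SimulationConfig(n_accessions=200, n_snps=400, n_subpops=2,
                               fst_like_divergence=0.2, seed=8)
        G, _, K = simulate_population(cfg)
        rng = np.random.default_rng(11)
        y = rng.standard_normal(200)
        X = (rng.random((200, 2000)) < rng.uniform(0.05, 0.5, 2000)).astype(float)
        p = emmax_scan(y, X, K.to_numpy())["p_value"].dropna()
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestGlmScan:
    def test_textbook_regression_fixture(self):
        # x = 1..6, y = 2x + (1, -1, 0, 1, -1, 0): closed-form slope/t
        x = np.arange(1.0, 7.0)
        y = 2 * x + np.array([1.0, -1.0, 0.0, 1.0, -1.0, 0.0])
        res = glm_scan(y, x[:, None])
        sxx = ((x - x.mean()) ** 2).sum()
        bhat = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        resid = y - y.mean() - bhat * (x - x.mean())
        s2 = (resid**2).sum() / 4
        se = np.sqrt(s2 / sxx)
        t = bhat / se
        assert res.iloc[0].beta == pytest.approx(bhat, rel=1e-12)
        assert res.iloc[0].p_value == pytest.approx(2 * stats.t.sf(abs(t), 4), rel=1e-10)

    def test_strong_effect_recovered(self):
        rng = np.random.default_rng(9)
        x = rng.integers(0, 2, 100).astype(float)
        y = 2 * x + 0.1 * rng.standard_normal(100)
        res = glm_scan(y, x[:, None])
        assert res.iloc[0].beta == pytest.approx(2.0, abs=0.1)
        assert res.iloc[0].p_value < 1e-10

    def test_glm_equals_emmax_with_identity_covariance(self):
        rng = np.random.default_rng(10)
        n = 40
        y = rng.standard_normal(n)
        X = rng.integers(0, 2, (n, 5)).astype(float)
        pg = glm_scan(y, X)["p_value"]
        pe = emmax_scan(y, X, np.eye(n))["p_value"]
        np.testing.assert_allclose(pg, pe, atol=1e-10)

    def test_collinear_covariates_rejected(self):
        y = np.zeros(10)
        X = np.ones((10, 1))
        with pytest.raises(ValueError, match="collinear"):
            glm_scan(y, X, C=np.ones((10, 1)))


class TestBurdenScanModel:
    def test_accession_intersection_and_summary(self, small_dataset):
        ds, _ = small_dataset
        res = BurdenScan(
            ds.expression, ds.truth.true_burden.loc[:, ds.truth.true_burden.mean() >= 0.05],
            kinship=ds.kinship, model="emmax",
        ).fit()
        assert set(res.frame["model"]) == {"emmax"}
        txt = res.summary()
        assert "emmax" in txt and "accessions" in txt

    def test_pc_sign_flip_leaves_p_unchanged(self, small_dataset):
        ds, _ = small_dataset
        pcs = compute_pcs(ds.genotypes, k=3)
        markers = ds.truth.true_burden.loc[:, ds.truth.true_burden.mean() >= 0.1].iloc[:, :5]
        pheno = ds.expression.iloc[:, :3]
        r1 = BurdenScan(pheno, markers, pcs=pcs, model="glm_pc").fit()
        r2 = BurdenScan(pheno, markers, pcs=-pcs, model="glm_pc").fit()
        np.testing.assert_allclose(
            r1.frame["p_value"], r2.frame["p_value"], rtol=1e-8
        )

    def test_planted_effect_detected(self, small_dataset):
        ds, _ = small_dataset
        causal, target, beta = ds.truth.true_effects[0]
        markers = ds.truth.true_burden.loc[:, ds.truth.true_burden.mean() > 0]
        res = BurdenScan(ds.expression[[target]], markers,
                         kinship=ds.kinship, model="emmax").fit()
        frame = res.frame.set_index("marker")
        assert frame.loc[causal, "p_value"] == frame["p_value"].min()
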