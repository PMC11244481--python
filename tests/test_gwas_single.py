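import numpy as np
import pytest
from scipy import stats

from ginfunnel.data_io import GenotypeMatrix, SnpRecord
from ginfunnel.gwas_single import (
    bonferroni_threshold,
    compute_kinship,
    compute_pcs,
    genomic_inflation,
    glm_scan,
    ld_prune,
    manhattan_qq_plot,
    mlm_scan,
    null_reml,
    run_six_models,
)
from ginfunnel.simulate import SimConfig, simulate_genotypes, simulate_trait


def gm_from_calls(calls, chrom="chr1"):
    calls = np.asarray(calls, dtype=np.int8)
    snps = [SnpRecord(f"s{j}", chrom, 100 * (j + 1), "A", "G") for j in range(calls.shape[1])]
    return GenotypeMatrix([f"S{i}" for i in range(calls.shape[0])], snps, calls)


class TestKinship:
    def test_identical_genotypes_have_equal_entries(self):
        gm = gm_from_calls([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]])
        k = compute_kinship(gm, stabilize=0.0).values
        assert k[0, 1] == pytest.approx(k[0, 0])
        assert k[0, 1] == pytest.approx(k[1, 1])

    def test_matches_hand_computed_formula(self):
        calls = np.array([[0, 1, 2, 0], [1, 1, 0, 2], [2, 0, 1, 1]], dtype=float)
        gm = gm_from_calls(calls)
        p = calls.mean(axis=0) / 2
        w = calls - 2 * p
        expected = w @ w.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(compute_kinship(gm, stabilize=0.0).values, expected, atol=1e-12)

    def test_symmetric_psd_on_random_fixtures(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            gm = gm_from_calls(rng.integers(0, 3, size=(8, 12)))
            k = compute_kinship(gm).values
            np.testing.assert_allclose(k, k.T, atol=1e-12)
            assert np.linalg.eigvalsh(k).min() > -1e-9

    def test_monomorphic_panel_rejected(self):
        gm = gm_from_calls(np.ones((4, 3)) * 2)
        with pytest.raises(ValueError):
            compute_kinship(gm)


class TestPcs:
    def test_separates_planted_subpopulations(self):
        cfg = SimConfig(n_samples=200, n_snps=500, n_chrom=5, n_subpops=2, fst=0.3, seed=21)
        gm = simulate_genotypes(cfg)
        labels = np.arange(200) % 2
        pcs = compute_pcs(gm, 2).scores
        r = abs(np.corrcoef(pcs[:, 0], labels)[0, 1])
        assert r > 0.9

    def test_zero_components_degenerate_case(self, desk_genotypes):
        pcs = compute_pcs(desk_genotypes, 0)
        assert pcs.scores.shape == (desk_genotypes.n_samples, 0)
        y = np.random.default_rng(0).normal(size=desk_genotypes.n_samples)
        a = glm_scan(desk_genotypes, y, None)
        b = glm_scan(desk_genotypes, y, pcs.scores)
        np.testing.assert_allclose([r.p for r in a], [r.p for r in b], atol=1e-12)

    def test_scores_orthogonal_and_mean_zero(self, desk_genotypes):
        s = compute_pcs(desk_genotypes, 4).scores
        gram = s.T @ s
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-6)
        np.testing.assert_allclose(s.mean(axis=0), 0, atol=1e-8)

    def test_q_too_large_rejected(self, small_genotypes):
        with pytest.raises(ValueError):
            compute_pcs(small_genotypes, small_genotypes.n_samples)


class TestLdPrune:
    def test_duplicated_snp_keeps_exactly_one(self):
        rng = np.random.default_rng(5)
        col = rng.integers(0, 3, size=50)
        calls = np.column_stack([col, col, rng.integers(0, 3, size=50)])
        gm = gm_from_calls(calls)
        kept = ld_prune(gm, window=3, step=3, r2_max=0.2)
        assert ("s0" in kept) != ("s1" in kept)
        assert "s2" in kept

    def test_independent_snps_mostly_retained(self):
        retained = []
        for seed in range(20):
            cfg = SimConfig(n_samples=300, n_snps=100, n_chrom=1, ld_rho=0.0, n_subpops=1, seed=seed)
            gm = simulate_genotypes(cfg)
            kept = ld_prune(gm)
            retained.append(len(kept) / gm.n_snps)
        assert np.mean(retained) >= 0.95

    def test_postcondition_no_retained_pair_exceeds_r2(self):
        cfg = SimConfig(n_samples=150, n_snps=200, n_chrom=2, ld_rho=0.95, ld_block_size=10, seed=17)
        gm = simulate_genotypes(cfg)
        kept = ld_prune(gm, window=50, step=50, r2_max=0.2)
        idx = [j for j, s in enumerate(gm.snps) if s.id in set(kept)]
        x = gm.dosage(impute=True)
        # brute-force verification within each pruning window
        for start in range(0, gm.n_snps, 50):
            win = [j for j in idx if start <= j < start + 50]
            for a in range(len(win)):
                for b in range(a + 1, len(win)):
                    r = np.corrcoef(x[:, win[a]], x[:, win[b]])[0, 1]
                    assert r**2 < 0.2 + 1e-9


class TestGlmScan:
    def test_perfect_fit_limits(self):
        rng = np.random.default_rng(0)
        calls = rng.integers(0, 3, size=(30, 3))
        gm = gm_from_calls(calls)
        y = calls[:, 1].astype(float) * 0.5
        res = glm_scan(gm, y)
        assert res[1].p < 1e-50 and res[1].pve > 0.999

    def test_matches_normal_equations_oracle(self, small_genotypes):
        rng = np.random.default_rng(1)
        y = rng.normal(0.6, 0.3, 12)
        cov = rng.normal(size=(12, 2))
        res = glm_scan(small_genotypes, y, cov)
        x = small_genotypes.dosage()
        for j, r in enumerate(res):
            X1 = np.column_stack([np.ones(12), cov, x[:, j]])
            X0 = np.column_stack([np.ones(12), cov])
            b1 = np.linalg.solve(X1.T @ X1, X1.T @ y)
            rss1 = float(np.sum((y - X1 @ b1) ** 2))
            b0 = np.linalg.solve(X0.T @ X0, X0.T @ y)
            rss0 = float(np.sum((y - X0 @ b0) ** 2))
            df2 = 12 - X1.shape[1]
            f = (rss0 - rss1) / (rss1 / df2)
            p = stats.f.sf(f, 1, df2)
            assert r.beta == pytest.approx(b1[-1], abs=1e-10)
            assert r.p == pytest.approx(p, abs=1e-10)

    def test_permutation_null_uniform_p(self):
        cfg = SimConfig(n_samples=200, n_snps=500, n_chrom=5, n_subpops=1, ld_rho=0.0, seed=33)
        gm = simulate_genotypes(cfg)
        rng = np.random.default_rng(33)
        y = rng.normal(0.6, 0.3, 200)
        res = glm_scan(gm, y)
        pvals = np.array([r.p for r in res if not r.flagged])
        _, ks_p = stats.kstest(pvals, "uniform")
        assert ks_p > 0.05

    def test_monomorphic_snp_flagged(self):
        calls = np.zeros((10, 2), dtype=np.int8)
        calls[:, 1] = np.random.default_rng(0).integers(0, 3, 10)
        gm = gm_from_calls(calls)
        res = glm_scan(gm, np.random.default_rng(1).normal(size=10))
        assert res[0].flagged and res[0].p == 1.0 and res[0].beta == 0.0


class TestMlmScan:
    def test_reduces_to_glm_without_relatedness(self):
        # unrelated samples: estimated polygenic variance ~ 0, so MLM == GLM
        cfg = SimConfig(n_samples=150, n_snps=300, n_chrom=3, ld_rho=0.0, n_subpops=1, seed=2)
        gm = simulate_genotypes(cfg)
        rng = np.random.default_rng(2)
        y = rng.normal(0.6, 0.3, 150)
        kin = compute_kinship(gm)
        null = null_reml(y, kin)
        if null["delta"] < 1e4:  # only meaningful when REML pushes delta high
            pytest.skip("REML found nonzero relatedness signal on this draw")
        glm = glm_scan(gm, y)
        mlm = mlm_scan(gm, y, kin, null_fit=null)
        np.testing.assert_allclose([r.p for r in mlm], [r.p for r in glm], atol=1e-6)

    def test_matches_grid_search_gls_oracle(self):
        rng = np.random.default_rng(7)
        calls = rng.integers(0, 3, size=(8, 5))
        gm = gm_from_calls(calls)
        y = rng.normal(0.6, 0.3, 8)
        kin = compute_kinship(gm)
        K = kin.values
        # dense grid-search REML over lambda = sigma_e^2 / sigma_g^2
        X = np.ones((8, 1))
        def reml_ll(delta):
            V = K + delta * np.eye(8)
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - X @ beta
            s2 = float(r @ Vi @ r) / (8 - 1)
            _, ldv = np.linalg.slogdet(V)
            _, ldx = np.linalg.slogdet(XtViX)
            return -0.5 * ((8 - 1) * np.log(s2) + ldv + ldx + (8 - 1))
        grid = np.geomspace(1e-4, 1e4, 20001)
        deltas = [reml_ll(d) for d in grid]
        d_star = grid[int(np.argmax(deltas))]
        null = null_reml(y, kin)
        assert np.log(null["delta"]) == pytest.approx(np.log(d_star), abs=1e-3)
        # per-marker GLS with the oracle delta
        V = K + d_star * np.eye(8)
        Vi = np.linalg.inv(V)
        L = np.linalg.cholesky(Vi)
        res = mlm_scan(gm, y, kin, null_fit=null)
        x = gm.dosage(impute=True)
        for j, r in enumerate(res):
            if r.flagged:
                continue
            X1 = np.column_stack([np.ones(8), x[:, j]])
            Xw, yw = L.T @ X1, L.T @ y
            b = np.linalg.lstsq(Xw, yw, rcond=None)[0]
            assert r.beta == pytest.approx(b[-1], abs=1e-4)

    def test_structured_population_calibration(self):
        glm_lams, mlm_lams = [], []
        for seed in range(10):
            cfg = SimConfig(n_samples=200, n_snps=600, n_chrom=6, n_subpops=2, fst=0.15,
                            ld_rho=0.0, seed=seed)
            gm = simulate_genotypes(cfg)
            rng = np.random.default_rng(seed + 500)
            y = rng.normal(0.6, 0.2, 200) + 0.25 * (np.arange(200) % 2)
            kin = compute_kinship(gm)
            glm_lams.append(genomic_inflation([r.p for r in glm_scan(gm, y)]))
            mlm_lams.append(genomic_inflation([r.p for r in mlm_scan(gm, y, kin)]))
        assert np.mean(glm_lams) > 1.2
        assert 0.9 <= np.mean(mlm_lams) <= 1.1


class TestThresholdAndPlots:
    @pytest.mark.parametrize(
        "n,fwer,expect_p,expect_log",
        [(39327, 0.01, 2.54e-7, 6.59), (1, 0.05, 0.05, 1.301), (100, 0.05, 5e-4, 3.301)],
    )
    def test_bonferroni_arithmetic(self, n, fwer, expect_p, expect_log):
        p, nl = bonferroni_threshold(n, fwer)
        assert p == pytest.approx(expect_p, rel=5e-3)
        assert nl == pytest.approx(expect_log, abs=5e-3)

    def test_plot_files_created(self, tmp_path, desk_genotypes):
        y = np.random.default_rng(0).normal(0.6, 0.3, desk_genotypes.n_samples)
        res = glm_scan(desk_genotypes, y)
        man, qq = manhattan_qq_plot(res, 2.54e-7, str(tmp_path / "plot"))
        import os
        assert os.path.getsize(man) > 0 and os.path.getsize(qq) > 0

    def test_empty_results_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            manhattan_qq_plot([], 0.05, str(tmp_path / "x"))


class TestSixModels:
    def test_all_models_cover_all_snps_with_one_schema(self, desk_genotypes):
        y = np.random.default_rng(4).normal(0.6, 0.3, desk_genotypes.n_samples)
        out = run_six_models(desk_genotypes, y)
        assert set(out) == {"GLM", "GLM_Q", "GLM_PCA", "MLM_K", "MLM_QK", "MLM_PCAK"}
        for tag, res in out.items():
            assert len(res) == desk_genotypes.n_snps
            assert all(r.model == tag for r in res)
            assert all(0 <= r.pve <= 1 and 0 < r.p <= 1 for r in res)
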