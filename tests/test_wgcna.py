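import numpy as np
import pytest
from scipy import special

from tests_helpers import make_expr
from ginfunnel.wgcna import (
    adjacency_matrix,
    correlation_pvalue,
    detect_modules,
    filter_expression,
    key_module,
    module_trait,
    pick_soft_threshold,
    remove_outlier_samples,
    scale_free_fit,
    select_hubs,
    tom_matrix,
)


def modular_expression(rng, n=100, sizes=(20, 15, 10), n_background=30):
    """Planted-module expression with per-gene loadings (hub structure)."""
    blocks = []
    truth = []
    for mi, size in enumerate(sizes):
        f = rng.standard_normal(n)
        for _ in range(size):
            lam = rng.uniform(0.5, 0.95)
            g = lam * f + np.sqrt(1 - lam**2) * rng.standard_normal(n)
            blocks.append(g)
            truth.append(mi)
    for _ in range(n_background):
        blocks.append(rng.standard_normal(n))
        truth.append(-1)
    values = np.exp(0.3 * np.array(blocks) + 1.0)
    return make_expr(values), np.array(truth)


def modular_expression_const(rng, n=100, sizes=(20, 15, 10), r_within=0.8, n_background=30):
    """Planted modules with constant within-module correlation r_within."""
    blocks = []
    truth = []
    lam = np.sqrt(r_within)
    for mi, size in enumerate(sizes):
        f = rng.standard_normal(n)
        for _ in range(size):
            blocks.append(lam * f + np.sqrt(1 - r_within) * rng.standard_normal(n))
            truth.append(mi)
    for _ in range(n_background):
        blocks.append(rng.standard_normal(n))
        truth.append(-1)
    return make_expr(np.exp(0.3 * np.array(blocks) + 1.0)), np.array(truth)


class TestFilter:
    def test_strictly_more_than_threshold_removed(self):
        n = 344
        vals = np.ones((3, n))
        vals[0, : int(0.7006 * n) + 1] = 0  # 241/344 ~ 70.06% zeros
        vals[1, : int(0.700 * n)] = 0       # exactly 70.0% -> retained
        expr = make_expr(vals)
        kept = filter_expression(expr)
        assert kept.genes == ["g1", "g2"]

    def test_paper_scale_narrowing(self):
        # 541 genes of which 131 are constructed to exceed the 70% rule
        rng = np.random.default_rng(0)
        n = 100
        vals = rng.uniform(0.5, 2.0, (541, n))
        zero_idx = rng.choice(541, size=131, replace=False)
        for gi in zero_idx:
            vals[gi, : 75] = 0.0  # 75% zeros
        kept = filter_expression(make_expr(vals))
        assert kept.n_genes == 410

    def test_all_removed_raises(self):
        vals = np.zeros((2, 10))
        with pytest.raises(ValueError):
            filter_expression(make_expr(vals))


class TestOutliers:
    def test_homogeneous_data_keeps_everyone(self):
        dropped_total = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            expr = make_expr(np.exp(rng.standard_normal((30, 40)) * 0.3 + 1))
            _, dropped = remove_outlier_samples(expr)
            dropped_total += len(dropped) > 0
        assert dropped_total <= 2

    def test_planted_outlier_dropped(self):
        rng = np.random.default_rng(1)
        vals = np.exp(rng.standard_normal((30, 40)) * 0.3 + 1)
        vals[:, 7] *= np.exp(10.0)  # 10-sigma shifted profile on log scale
        expr = make_expr(vals)
        filtered, dropped = remove_outlier_samples(expr)
        assert dropped == ["S7"]
        assert "S7" not in filtered.samples

    def test_two_samples_no_op(self):
        expr = make_expr([[1.0, 2.0], [2.0, 1.0]])
        out, dropped = remove_outlier_samples(expr)
        assert dropped == [] and out.n_samples == 2

    def test_mass_flagging_requires_force(self):
        rng = np.random.default_rng(2)
        vals = np.exp(rng.standard_normal((20, 10)) * 0.1)
        vals[:, :4] *= np.exp(rng.uniform(5, 9, (20, 4)))  # 40% extreme
        with pytest.raises(ValueError, match="force"):
            remove_outlier_samples(make_expr(vals))
        out, dropped = remove_outlier_samples(make_expr(vals), force=True)
        assert len(dropped) >= 3


class TestSoftThreshold:
    def test_identity_correlated_duplicates_connectivity(self):
        base = np.linspace(1, 5, 20)
        vals = np.tile(base, (6, 1))
        a = adjacency_matrix(make_expr(vals), power=1.0)
        k = a.sum(axis=1)
        np.testing.assert_allclose(k, 5.0, atol=1e-10)

    def test_modular_data_reaches_fit_target(self):
        hits = 0
        for seed in range(10):
            expr, _ = modular_expression(np.random.default_rng(seed))
            rep = pick_soft_threshold(expr, powers=np.arange(1.0, 20.5, 1.0), r2_target=0.8)
            hits += rep.fit_r2.max() >= 0.8
        assert hits >= 8

    def test_fit_matches_independent_binning_oracle(self):
        rng = np.random.default_rng(5)
        expr, _ = modular_expression(rng, n=60, sizes=(8, 6), n_background=6)
        a = adjacency_matrix(expr, 6.0)
        k = a.sum(axis=1)
        got = scale_free_fit(k, n_bins=10)
        # oracle: explicit re-binned log-log regression
        kk = k[k > 0]
        edges = np.linspace(kk.min(), kk.max() + 1e-12, 11)
        which = np.digitize(kk, edges[1:-1])
        xs, ys = [], []
        for b in range(10):
            m = kk[which == b]
            if m.size:
                xs.append(np.log10(m.mean()))
                ys.append(np.log10(m.size / kk.size))
        X = np.column_stack([np.ones(len(xs)), xs])
        beta = np.linalg.lstsq(X, ys, rcond=None)[0]
        resid = ys - X @ beta
        r2 = 1 - resid @ resid / np.sum((ys - np.mean(ys)) ** 2)
        expected = -np.sign(beta[1]) * r2
        assert got == pytest.approx(expected, abs=1e-10)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            pick_soft_threshold(make_expr([[1.0, 2.0, 3.0], [2.0, 1.0, 3.0]]))


class TestTom:
    def test_isolated_pair_closed_form(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        t = tom_matrix(a)
        assert t[0, 1] == pytest.approx(1.0)
        assert t[2, 3] == 0.0

    def test_disconnected_graph_all_zero_offdiag(self):
        t = tom_matrix(np.zeros((5, 5)))
        assert np.allclose(t - np.eye(5), 0)

    def test_matches_triple_loop_brute_force(self):
        rng = np.random.default_rng(9)
        r = rng.uniform(0, 1, (12, 12))
        a = (r + r.T) / 2
        np.fill_diagonal(a, 0.0)
        t = tom_matrix(a)
        n = 12
        for i in range(n):
            for j in range(n):
                if i == j:
                    assert t[i, j] == 1.0
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                expected = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
                assert t[i, j] == pytest.approx(expected, abs=1e-12)

    def test_entries_in_unit_interval_random_fixtures(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            r = rng.uniform(0, 1, (10, 10))
            a = (r + r.T) / 2
            np.fill_diagonal(a, 0)
            t = tom_matrix(a)
            assert np.all(t >= -1e-12) and np.all(t <= 1 + 1e-12)
            np.testing.assert_allclose(t, t.T, atol=1e-12)

    def test_asymmetric_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError):
            tom_matrix(a)


class TestModules:
    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        aris = []
        for seed in range(10):
            expr, truth = modular_expression_const(np.random.default_rng(seed))
            a = adjacency_matrix(expr, 6.0)
            t = tom_matrix(a)
            modules = detect_modules(t, expr.genes, min_module_size=5)
            label_of = {}
            for mi, mod in enumerate(modules):
                for g in mod.genes:
                    label_of[g] = -1 if mod.color == "grey" else mi
            pred = [label_of[g] for g in expr.genes]
            aris.append(adjusted_rand_score(truth, pred))
        assert np.mean(aris) >= 0.8

    def test_independent_genes_mostly_grey(self):
        greys = []
        for seed in range(5):
            rng = np.random.default_rng(seed + 40)
            expr = make_expr(np.exp(0.3 * rng.standard_normal((60, 80))))
            a = adjacency_matrix(expr, 6.0)
            modules = detect_modules(tom_matrix(a), expr.genes, min_module_size=5)
            grey = next((m for m in modules if m.color == "grey"), None)
            greys.append(len(grey.genes) / 60 if grey else 0)
        assert np.mean(greys) >= 0.9

    def test_min_module_size_respected(self):
        expr, _ = modular_expression(np.random.default_rng(3))
        modules = detect_modules(tom_matrix(adjacency_matrix(expr, 6.0)), expr.genes)
        for m in modules:
            if m.color != "grey":
                assert len(m.genes) >= 5

    def test_determinism(self):
        expr, _ = modular_expression(np.random.default_rng(12))
        t = tom_matrix(adjacency_matrix(expr, 6.0))
        a = detect_modules(t, expr.genes)
        b = detect_modules(t, expr.genes)
        assert [(m.color, m.genes) for m in a] == [(m.color, m.genes) for m in b]


class TestModuleTrait:
    def test_eigengene_equal_to_trait_gives_r_one(self):
        n = 50
        trait = np.linspace(0, 1, n)
        vals = np.exp(np.tile(trait, (6, 1)) + 0.0)
        expr = make_expr(vals)
        from ginfunnel.wgcna import CoexprModule

        mods = module_trait([CoexprModule("turquoise", expr.genes)], expr, trait)
        assert abs(mods[0].trait_r) > 0.99
        assert mods[0].trait_p < 1e-20

    def test_planted_correlation_envelope(self):
        rs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 344
            trait = rng.normal(0.6, 0.3, n)
            t_std = (trait - trait.mean()) / trait.std()
            f = 0.85 * t_std + np.sqrt(1 - 0.85**2) * rng.standard_normal(n)
            vals = np.exp(0.3 * np.array([
                0.9 * f + np.sqrt(1 - 0.81) * rng.standard_normal(n) for _ in range(10)
            ]))
            expr = make_expr(vals)
            from ginfunnel.wgcna import CoexprModule

            mods = module_trait([CoexprModule("turquoise", expr.genes)], expr, trait)
            rs.append(abs(mods[0].trait_r))
        assert 0.75 <= np.mean(rs) <= 0.95

    def test_p_matches_incomplete_beta_oracle(self):
        r, n = 0.85, 42
        p = correlation_pvalue(r, n)
        # two-sided p via the incomplete beta function of the t distribution
        t = r * np.sqrt((n - 2) / (1 - r**2))
        df = n - 2
        oracle = special.betainc(df / 2, 0.5, df / (df + t**2))
        assert p == pytest.approx(oracle, abs=1e-10)

    def test_key_module_is_max_abs_r(self):
        from ginfunnel.wgcna import CoexprModule

        mods = [CoexprModule("a", ["g"]), CoexprModule("b", ["h"]), CoexprModule("c", ["i"])]
        mods[0].trait_r, mods[1].trait_r, mods[2].trait_r = 0.4, -0.9, 0.7
        assert key_module(mods).color == "b"


class TestHubs:
    def test_star_center_is_top_hub(self):
        from ginfunnel.wgcna import CoexprModule

        genes = ["center", "a", "b", "c", "d"]
        adj = np.zeros((5, 5))
        for j in range(1, 5):
            adj[0, j] = adj[j, 0] = 0.9
        hubs = select_hubs(CoexprModule("m", genes), adj, genes, weight_min=0.4, top_k=1)
        assert hubs == ["center"]

    def test_small_module_returns_all_members(self):
        from ginfunnel.wgcna import CoexprModule

        genes = ["a", "b", "c"]
        adj = np.full((3, 3), 0.8)
        np.fill_diagonal(adj, 0)
        hubs = select_hubs(CoexprModule("m", genes), adj, genes, top_k=5)
        assert sorted(hubs) == genes

    def test_ranks_match_brute_force_weighted_degree(self):
        from ginfunnel.wgcna import CoexprModule

        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(10)]
        r = rng.uniform(0, 1, (10, 10))
        adj = (r + r.T) / 2
        np.fill_diagonal(adj, 0)
        hubs = select_hubs(CoexprModule("m", genes), adj, genes, weight_min=0.4, top_k=5)
        thr = adj.copy()
        thr[thr <= 0.4] = 0
        deg = thr.sum(axis=1)
        expected = [genes[i] for i in sorted(range(10), key=lambda i: (-deg[i], genes[i]))[:5]]
        assert hubs == expected

    def test_no_surviving_edge_returns_empty(self):
        from ginfunnel.wgcna import CoexprModule

        genes = ["a", "b"]
        adj = np.array([[0, 0.1], [0.1, 0]])
        assert select_hubs(CoexprModule("m", genes), adj, genes, weight_min=0.4) == []
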