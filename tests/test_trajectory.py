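import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from scburden.simulate import LineageSimConfig, LineageView, simulate_lineage
from scburden.trajectory import (
    KnnGraph,
    build_knn_graph,
    combine_p_logit,
    common_grid,
    de_score,
    make_metacells,
    morans_test,
    pathway_trajectory,
    pattern_test,
    select_dynamic_genes,
    smooth_curve,
    MoranResult,
)


class TestKnnGraph:
    def test_collinear_points_symmetrized(self):
        emb = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        g = build_knn_graph(emb, k=1)
        # middle node is connected to both ends after union symmetrization
        assert g.weights[1, 0] > 0 and g.weights[1, 2] > 0
        assert g.weights[0, 2] == 0

    def test_k_saturates_to_complete_graph(self):
        emb = np.random.default_rng(0).normal(size=(6, 2))
        g = build_knn_graph(emb, k=5)  # k = N - 1
        off_diag = g.weights + np.eye(6)
        assert (off_diag > 0).all()

    def test_neighbors_match_brute_force(self):
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(100, 2))
        k = 5
        g = build_knn_graph(emb, k)
        d2 = ((emb[:, None, :] - emb[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for i in range(100):
            mine = set(np.flatnonzero(g.weights[i] > 0))
            knn_i = set(np.argsort(d2[i], kind="stable")[:k])
            rknn = {j for j in range(100) if i in set(np.argsort(d2[j], kind="stable")[:k])}
            assert mine == (knn_i | rknn)

    def test_row_standardized(self):
        emb = np.random.default_rng(1).normal(size=(30, 2))
        g = build_knn_graph(emb, 4)
        np.testing.assert_allclose(g.weights.sum(axis=1), 1.0)


class TestMoransTest:
    def test_path_graph_worked_example(self):
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            w[i, j] = w[j, i] = 1.0
        r = morans_test([1.0, 2.0, 3.0, 4.0], KnnGraph(weights=w))
        assert r.I == pytest.approx(1.0 / 3.0)
        assert r.expected_I == pytest.approx(-1.0 / 3.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_matches_brute_force_double_sum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        w = rng.random((n, n)) * (rng.random((n, n)) < 0.6)
        w = w + w.T
        np.fill_diagonal(w, 0)
        w[w.sum(1) == 0, rng.integers(0, n)] = 0.5  # no isolated nodes
        w = np.maximum(w, w.T)
        y = rng.normal(size=n)
        r = morans_test(y, KnnGraph(weights=w.copy()))
        res = y - y.mean()
        brute = 0.0
        for i in range(n):
            for j in range(n):
                brute += w[i, j] * res[i] * res[j]
        brute *= n / (w.sum() * (res**2).sum())
        assert r.I == pytest.approx(brute, abs=1e-10)

    def test_permutation_null_z_is_standard_normal(self):
        rng = np.random.default_rng(4)
        emb = rng.normal(size=(80, 2))
        g = build_knn_graph(emb, 6)
        y = rng.normal(size=80)
        zs = [morans_test(rng.permutation(y), g).z for _ in range(1000)]
        assert stats.kstest(zs, "norm").pvalue > 0.01

    def test_covariate_column_gives_zero_variance(self):
        rng = np.random.default_rng(5)
        emb = rng.normal(size=(30, 2))
        g = build_knn_graph(emb, 4)
        cov = rng.normal(size=30)
        X = np.column_stack([np.ones(30), cov])
        r = morans_test(cov, g, X)
        assert r.status == "zero variance"

    def test_covariates_remove_confounded_signal(self):
        # signal equal to a covariate shows autocorrelation without adjustment
        # but none after residualization
        rng = np.random.default_rng(6)
        t = np.sort(rng.uniform(0, 10, 200))
        emb = np.column_stack([t, rng.normal(0, 0.1, 200)])
        g = build_knn_graph(emb, 8)
        y = t + rng.normal(0, 0.05, 200)
        plain = morans_test(y, g)
        adj = morans_test(y, g, np.column_stack([np.ones(200), t]))
        assert plain.z > 10
        assert adj.z < 5


class TestSelectDynamicGenes:
    def _results(self, zs):
        out = {}
        for i, z in enumerate(zs):
            p = float(stats.norm.sf(z))
            out[f"g{i}"] = MoranResult(I=z / 100, expected_I=0, var_I=1, z=z, p=p)
        return out

    def test_threshold_bounds(self):
        res = self._results([50, 30, 1, -2])
        assert select_dynamic_genes(res, stat_min=np.inf) == set()
        assert select_dynamic_genes(res, q_max=1.0, stat_min=-np.inf) == {
            "g0", "g1", "g2", "g3"
        }
        assert select_dynamic_genes(res) == {"g0", "g1"}


class TestMetaCells:
    def _lineage(self, n_cells, n_genes=5, seed=0):
        cfg = LineageSimConfig(
            n_cells_per_condition=n_cells, n_genes=n_genes, frac_dynamic=0.0,
            noise_sd=0.0, seed=seed,
        )
        return simulate_lineage(cfg)

    def test_constant_gene_stays_constant(self):
        d, view, _ = self._lineage(200)
        mcs = make_metacells(view, d, n_meta=50)
        for mc in mcs.values():
            col = mc.values.iloc[:, 0]
            assert col.std() == pytest.approx(0.0, abs=1e-12)

    def test_five_hundred_metacells_from_thousand_cells(self):
        d, view, _ = self._lineage(1000)
        mc = make_metacells(view, d, n_meta=500, condition="control")
        assert len(mc.pseudotime) == 500
        assert (np.diff(mc.pseudotime) >= 0).all()
        assert mc.window == 20  # ceil(1000 / 50)

    def test_linear_gene_window_mean_bias_bound(self):
        # for y = t the window mean deviates from window-center pseudotime by
        # less than half the window's pseudotime width
        cfg = LineageSimConfig(
            n_cells_per_condition=400, n_genes=3, frac_dynamic=0.0,
            noise_sd=0.0, seed=1,
        )
        d, view, _ = simulate_lineage(cfg)
        import scipy.sparse as sp

        dense = np.asarray(d.norm.todense())
        order = {c: i for i, c in enumerate(d.cells.index)}
        pos = [order[c] for c in view.cell_ids]
        dense[0, pos] = view.pseudotime
        d.norm = sp.csr_matrix(dense)
        mc = make_metacells(view, d, n_meta=100, condition="control")
        np.testing.assert_allclose(
            mc.values.iloc[:, 0].to_numpy(), mc.pseudotime, atol=1e-9
        )

    def test_metacell_mean_matches_cell_mean(self):
        d, view, _ = self._lineage(500, seed=2)
        mcs = make_metacells(view, d, n_meta=500)
        mask = view.condition == "control"
        cols = d.cells.index.get_indexer(view.cell_ids[mask])
        cell_mean = np.asarray(d.norm[:, cols].todense()).mean(axis=1)
        meta_mean = mcs["control"].values.mean(axis=0).to_numpy()
        np.testing.assert_allclose(meta_mean, cell_mean, atol=0.05)


class TestSmoothingAndScore:
    def _metacells(self, values, t):
        from scburden.trajectory import MetaCellMatrix

        return MetaCellMatrix(
            values=pd.DataFrame({"g": values}), pseudotime=np.asarray(t, float),
            condition="control",
        )

    def test_constant_reproduced(self):
        t = np.linspace(0, 10, 50)
        m = self._metacells(np.full(50, 3.3), t)
        _, fitted = smooth_curve(m, "g")
        np.testing.assert_allclose(fitted, 3.3, atol=1e-9)

    def test_linear_signal_exact(self):
        t = np.linspace(0, 10, 80)
        m = self._metacells(2.0 * t + 1.0, t)
        grid, fitted = smooth_curve(m, "g")
        interior = (grid > 0.5) & (grid < 9.5)
        np.testing.assert_allclose(fitted[interior], 2.0 * grid[interior] + 1.0, atol=1e-6)

    def test_smoothing_contracts_variance(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 10, 100)
        y = 1.0 + rng.normal(0, 0.5, 100)
        m = self._metacells(y, t)
        _, fitted = smooth_curve(m, "g", span=1.0)
        assert fitted.var() < y.var()

    def test_too_few_metacells_rejected(self):
        m = self._metacells(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError, match="10 meta-cells"):
            smooth_curve(m, "g")

    def test_de_score_examples(self):
        grid = np.linspace(0, 10, 200)
        auc_c, auc_d, score, called = de_score(grid, np.ones(200), np.full(200, 2.0))
        assert auc_c == pytest.approx(10.0)
        assert auc_d == pytest.approx(20.0)
        assert score == pytest.approx(10.0)
        assert not called
        same = np.sin(grid)
        assert de_score(grid, same, same)[2] == 0.0
        assert de_score(grid, np.zeros(200), np.full(200, 4.99), threshold=50)[3] is False
        assert de_score(grid, np.zeros(200), np.full(200, 5.0), threshold=50)[3] is True

    def test_de_score_shift_invariant_scale_linear(self):
        rng = np.random.default_rng(2)
        grid = np.linspace(0, 10, 100)
        a, b = rng.random(100), rng.random(100)
        s0 = de_score(grid, a, b)[2]
        assert de_score(grid, a + 5, b + 5)[2] == pytest.approx(s0)
        assert de_score(grid, 3 * a, 3 * b)[2] == pytest.approx(3 * s0)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            de_score(np.linspace(0, 1, 10), np.ones(10), np.ones(9))


class TestPatternAndPathways:
    def test_null_pattern_p_uniformish(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0, 10, 300)
        labels = (np.arange(300) % 2 == 0).astype(int)
        ps = [
            pattern_test(t, rng.normal(size=300), labels, n_perm=49, seed=s)
            for s in range(40)
        ]
        assert min(ps) > 0.01 or np.mean(np.array(ps) < 0.2) < 0.5
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_divergent_bump_detected_and_scored(self):
        cfg = LineageSimConfig(
            n_cells_per_condition=400, n_genes=30, frac_dynamic=0.4,
            frac_divergent=0.5, divergence_amplitude=2.0, noise_sd=0.1,
            pseudotime_range=(0.0, 10.0), seed=9,
        )
        d, view, truth = simulate_lineage(cfg)
        mcs = make_metacells(view, d, n_meta=200)
        gene = sorted(truth.divergent_genes)[0]
        grid = common_grid(mcs["control"], mcs["case"], 200)
        _, cc = smooth_curve(mcs["control"], gene, grid=grid)
        _, cd = smooth_curve(mcs["case"], gene, grid=grid)
        score = de_score(grid, cc, cd)[2]
        assert score == pytest.approx(10.0, rel=0.15)
        a, b = mcs["control"], mcs["case"]
        p = pattern_test(
            np.concatenate([a.pseudotime, b.pseudotime]),
            np.concatenate([a.values[gene], b.values[gene]]),
            np.concatenate([np.zeros(len(a.pseudotime), int), np.ones(len(b.pseudotime), int)]),
            n_perm=199,
            seed=1,
        )
        assert p < 0.01

    def test_pathway_singleton_equals_gene_curve(self):
        cfg = LineageSimConfig(n_cells_per_condition=300, n_genes=10,
                               frac_dynamic=0.5, noise_sd=0.1, seed=3)
        d, view, _ = simulate_lineage(cfg)
        mcs = make_metacells(view, d, n_meta=100)
        gene = d.genes.index[0]
        out = pathway_trajectory(mcs, {gene}, n_perm=19)
        m = mcs["control"]
        expected = smooth_curve(
            m, gene, grid=out["grid"]
        )
        # singleton pathway: aggregate is log1p of the gene itself
        logm = np.log1p(m.values[[gene]].to_numpy()).ravel()
        from scburden.trajectory import _local_linear

        ref = _local_linear(m.pseudotime, logm, out["grid"], 0.3)
        np.testing.assert_allclose(out["curves"]["control"], ref, atol=1e-12)

    def test_missing_set_rejected(self):
        cfg = LineageSimConfig(n_cells_per_condition=100, n_genes=5, seed=4)
        d, view, _ = simulate_lineage(cfg)
        mcs = make_metacells(view, d, n_meta=50)
        with pytest.raises(ValueError, match="no gene"):
            pathway_trajectory(mcs, {"ABSENT"})


class TestCombinePLogit:
    def test_all_half_is_half(self):
        assert combine_p_logit([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_two_tenths_worked_example(self):
        assert combine_p_logit([0.1, 0.1]) == pytest.approx(0.043, abs=0.001)

    def test_single_p_close_to_identity(self):
        for p in np.linspace(0.01, 0.99, 25):
            assert combine_p_logit([p]) == pytest.approx(p, abs=0.01)

    def test_boundary_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            out = combine_p_logit([0.0, 0.5])
        assert 0 < out < 0.5
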