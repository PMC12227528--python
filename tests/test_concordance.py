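import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from scburden.concordance import (
    GeneList,
    TFTargetMap,
    cluster_similarity,
    fc_correlation,
    fisher_overlap,
    hypergeom_enrichment,
    read_gene_list,
    read_gmt,
    read_tf_target_map,
    risk_gene_filter,
    tf_target_coverage,
)
from conftest import make_dataset


def _gl(name, genes):
    return GeneList(name=name, genes=set(genes))


def _brute_hypergeom_p(background, reference, sample_size, overlap):
    """P(overlap >= observed) by direct enumeration over all draws."""
    total = comb(background, sample_size)
    count = 0
    for k in range(overlap, min(reference, sample_size) + 1):
        count += comb(reference, k) * comb(background - reference, sample_size - k)
    return count / total


class TestHypergeomEnrichment:
    def test_worked_example_66_over_252(self):
        bg = [f"g{i}" for i in range(10)]
        ref = bg[:4]
        sample = bg[1:4] + bg[5:7]  # overlap 3 with reference
        res = hypergeom_enrichment(_gl("s", sample), _gl("r", ref), _gl("b", bg))
        assert res.overlap == 3
        assert res.p == pytest.approx(66 / 252)
        assert res.fold_enrichment == pytest.approx((3 / 5) / (4 / 10))

    def test_no_overlap_p_near_one(self):
        bg = [f"g{i}" for i in range(100)]
        res = hypergeom_enrichment(_gl("s", bg[:30]), _gl("r", bg[98:]), _gl("b", bg))
        assert res.overlap == 0
        assert res.p > 0.4

    def test_degenerate_certainty(self):
        bg = [f"g{i}" for i in range(8)]
        res = hypergeom_enrichment(_gl("s", bg), _gl("r", bg), _gl("b", bg))
        assert res.overlap == 8
        assert res.p == pytest.approx(1.0)

    def test_sample_clipped_to_background(self):
        bg = [f"g{i}" for i in range(10)]
        res = hypergeom_enrichment(
            _gl("s", bg[:3] + ["alien"]), _gl("r", bg[:5]), _gl("b", bg)
        )
        assert res.clipped == 1
        assert res.sample_size == 3

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_matches_enumeration_small_backgrounds(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(6, 26))
        bg = [f"g{i}" for i in range(m)]
        n_ref = int(rng.integers(1, m))
        n_samp = int(rng.integers(1, m))
        ref = list(rng.choice(bg, n_ref, replace=False))
        samp = list(rng.choice(bg, n_samp, replace=False))
        res = hypergeom_enrichment(_gl("s", samp), _gl("r", ref), _gl("b", bg))
        brute = _brute_hypergeom_p(m, n_ref, n_samp, res.overlap)
        assert res.p == pytest.approx(brute, abs=1e-12)


class TestFisherOverlap:
    def test_worked_example_3113(self):
        u = [f"g{i}" for i in range(8)]
        a = u[:4]                # row margin 4
        b = u[1:4] + [u[5]]      # overlap 3, table [[3,1],[1,3]]
        p, odds = fisher_overlap(_gl("a", a), _gl("b", b), _gl("u", u))
        assert p == pytest.approx(0.4857, abs=1e-3)
        assert odds == pytest.approx(9.0)

    def test_perfect_partition_extreme(self):
        u = [f"g{i}" for i in range(12)]
        a = u[:6]
        p_match, _ = fisher_overlap(_gl("a", a), _gl("b", a), _gl("u", u))
        p_disjoint, _ = fisher_overlap(_gl("a", a), _gl("b", u[6:]), _gl("u", u))
        assert p_match == pytest.approx(2 / comb(12, 6))
        assert p_disjoint == pytest.approx(2 / comb(12, 6))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_overlap(_gl("a", []), _gl("b", []), _gl("u", []))

    def test_independent_lists_uniform_p(self):
        rng = np.random.default_rng(0)
        u = [f"g{i}" for i in range(60)]
        ps = []
        for _ in range(400):
            a = rng.choice(u, 20, replace=False)
            b = rng.choice(u, 20, replace=False)
            ps.append(fisher_overlap(_gl("a", a), _gl("b", b), _gl("u", u))[0])
        from scipy import stats

        # Fisher p is discrete and conservative; check no inflation at 5%
        assert np.mean(np.asarray(ps) < 0.05) <= 0.07


class TestFCCorrelation:
    @staticmethod
    def _frame(fc, called=None):
        idx = [f"g{i}" for i in range(len(fc))]
        return pd.DataFrame(
            {"log2fc_model": fc,
             "called": called if called is not None else [True] * len(fc)},
            index=idx,
        )

    def test_identity_r_one(self):
        a = self._frame(np.linspace(-2, 2, 30))
        out = fc_correlation(a, a.copy())
        assert out["r"] == pytest.approx(1.0)
        assert out["sign_concordance"] == 1.0

    def test_antisymmetry(self):
        a = self._frame(np.linspace(-2, 2, 30))
        b = self._frame(-np.linspace(-2, 2, 30))
        assert fc_correlation(a, b)["r"] == pytest.approx(-1.0)

    def test_too_few_shared_rejected(self):
        a = self._frame([1.0, 2.0])
        with pytest.raises(ValueError, match="3 shared"):
            fc_correlation(a, a)

    def test_zero_variance_status(self):
        a = self._frame([1.0, 1.0, 1.0, 1.0])
        out = fc_correlation(a, self._frame([0.1, 0.2, 0.3, 0.4]))
        assert out["status"] == "undefined correlation"

    def test_independent_results_uncorrelated(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            a = self._frame(rng.normal(size=50))
            b = self._frame(rng.normal(size=50))
            if fc_correlation(a, b)["p"] < 0.05:
                hits += 1
        assert hits <= 10


class TestTFTargetCoverage:
    def test_direct_count(self):
        tfmap = TFTargetMap({"TF1": {"g1", "g2"}})
        out = tf_target_coverage(
            _gl("tf", ["TF1"]), tfmap, _gl("t", ["g1", "g3"]),
            _gl("b", ["g1", "g2", "g3", "g4", "TF1"]),
        )
        assert out["coverage"] == pytest.approx(0.5)

    def test_saturating_map(self):
        bg = [f"g{i}" for i in range(10)]
        tfmap = TFTargetMap({"TF1": set(bg)})
        out = tf_target_coverage(_gl("tf", ["TF1"]), tfmap, _gl("t", bg[:4]), _gl("b", bg))
        assert out["coverage"] == 1.0
        assert out["enrichment"].p == pytest.approx(1.0)

    def test_absent_tfs_undefined(self):
        tfmap = TFTargetMap({"TF1": {"g1"}})
        out = tf_target_coverage(_gl("tf", ["OTHER"]), tfmap, _gl("t", ["g1"]), _gl("b", ["g1"]))
        assert np.isnan(out["coverage"])
        assert out["n_tfs"] == 0

    def test_regulon_enrichment_detected(self):
        rng = np.random.default_rng(2)
        bg = [f"g{i}" for i in range(500)]
        targets = set(rng.choice(bg, 100, replace=False))
        tfmap = TFTargetMap({"TF1": targets})
        degs = set(rng.choice(sorted(targets), 40, replace=False)) | set(
            rng.choice(bg, 10, replace=False)
        )
        out = tf_target_coverage(_gl("tf", ["TF1"]), tfmap, _gl("t", degs), _gl("b", bg))
        assert out["enrichment"].p < 0.01


class TestClusterSimilarity:
    @staticmethod
    def _labelled_dataset(seed=0, n_genes=60, n_cells=90):
        rng = np.random.default_rng(seed)
        base = rng.gamma(2.0, 2.0, size=(n_genes, 3))  # per-cluster signature
        labels = np.repeat(["A", "B", "C"], n_cells // 3)
        lam = base[:, np.array([{"A": 0, "B": 1, "C": 2}[l] for l in labels])]
        counts = rng.poisson(lam * 5)
        d = make_dataset(counts)
        return d, pd.Series(labels, index=d.cells.index)

    def test_self_similarity_diagonal_maximal(self):
        d, labels = self._labelled_dataset()
        m = cluster_similarity(d, labels, d, labels)
        for c in m.index:
            assert m.loc[c, c] == pytest.approx(1.0)
            assert m.loc[c].idxmax() == c

    def test_gene_permutation_decouples(self):
        d, labels = self._labelled_dataset()
        rng = np.random.default_rng(3)
        d2 = d.copy()
        perm = rng.permutation(d.n_genes)
        d2.counts = d2.counts[perm]
        m = cluster_similarity(d, labels, d2, labels)
        assert m.to_numpy().max() < 0.8

    def test_matched_clusters_are_mutual_best_hits(self):
        d1, l1 = self._labelled_dataset(seed=4)
        d2, l2 = self._labelled_dataset(seed=5)  # same signatures, new noise? no:
        # regenerate second dataset sharing the signature matrix
        rng = np.random.default_rng(6)
        base = np.random.default_rng(4).gamma(2.0, 2.0, size=(60, 3))
        labels = np.repeat(["A", "B", "C"], 30)
        lam = base[:, np.array([{"A": 0, "B": 1, "C": 2}[l] for l in labels])]
        d2 = make_dataset(rng.poisson(lam * 5))
        l2 = pd.Series(labels, index=d2.cells.index)
        m = cluster_similarity(d1, l1, d2, l2)
        for c in ["A", "B", "C"]:
            assert m.loc[c].idxmax() == c
            assert m[c].idxmax() == c

    def test_tiny_cluster_excluded_with_warning(self):
        d, labels = self._labelled_dataset()
        labels.iloc[:2] = "tiny"
        labels.iloc[2:30] = "A"
        with pytest.warns(UserWarning, match="tiny"):
            m = cluster_similarity(d, labels, d, labels)
        assert "tiny" not in m.index


class TestListIO:
    def test_gene_list_and_risk_filter(self, tmp_path):
        path = tmp_path / "risk.tsv"
        path.write_text("GENE1\t1\nGENE2\t3\nGENE3\tsyndromic\nGENE4\t5\nGENE5\n")
        gl = read_gene_list(path, name="risk")
        assert len(gl) == 5
        filtered = risk_gene_filter(gl)
        assert filtered.genes == {"GENE1", "GENE2", "GENE3"}

    def test_gmt_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("SET_A\tdesc\tg1\tg2\tg3\nSET_B\tdesc\tg9\n")
        sets = read_gmt(path)
        assert sets["SET_A"].genes == {"g1", "g2", "g3"}
        assert sets["SET_B"].genes == {"g9"}

    def test_tf_map_reader_and_empty_set_rejected(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("TF1\tg1\nTF1\tg2\nTF2\tg3\n")
        tfmap = read_tf_target_map(path)
        assert tfmap.targets == {"TF1": {"g1", "g2"}, "TF2": {"g3"}}
        with pytest.raises(ValueError, match="empty target"):
            TFTargetMap({"TFX": set()})

    def test_order_and_duplicate_safety(self):
        a1 = hypergeom_enrichment(
            _gl("s", ["g1", "g2", "g2"]), _gl("r", ["g2", "g1"]),
            _gl("b", [f"g{i}" for i in range(6)]),
        )
        a2 = hypergeom_enrichment(
            _gl("s", ["g2", "g1"]), _gl("r", ["g1", "g2"]),
            _gl("b", [f"g{i}" for i in reversed(range(6))]),
        )
        assert a1.p == a2.p and a1.overlap == a2.overlap
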