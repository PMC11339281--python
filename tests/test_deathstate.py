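import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import oracles
from conftest import expression_from_dense
from nkfate.genesets import CANONICAL_PARADIGMS, GeneSet
from nkfate.deathstate import (
    ClassificationError,
    EnrichmentResult,
    RankedList,
    assign_paradigms,
    benjamini_hochberg,
    gsea_es,
    gsea_permutation,
    rank_cluster_genes,
    two_step_cluster,
)
from nkfate.io_qc import Embedding


def embedding_from_coords(coords):
    coords = np.asarray(coords, float)
    n = len(coords)
    return Embedding(
        coords=coords,
        loadings=np.zeros((1, coords.shape[1])),
        explained_variance_ratio=np.ones(coords.shape[1]) / coords.shape[1],
        k=coords.shape[1],
        hvgs=np.array(["G"]),
        barcodes=np.array([f"C{i}" for i in range(n)], dtype=object),
        cell_meta=pd.DataFrame(index=[f"C{i}" for i in range(n)]),
    )


class TestTwoStepCluster:
    def test_three_separated_blobs_recovered_exactly(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10]], float)
        labels = np.repeat([0, 1, 2], 120)
        coords = centers[labels] + rng.normal(0, 0.1, size=(360, 2))
        out = two_step_cluster(embedding_from_coords(coords), k_micro=30, seed=0)
        assert out.n_clusters == 3
        assert adjusted_rand_score(labels, out.labels) == 1.0

    def test_identical_points_form_one_community(self):
        coords = np.ones((50, 3))
        out = two_step_cluster(embedding_from_coords(coords), k_micro=5, seed=0)
        assert out.n_clusters == 1

    def test_seed_determinism(self, rng):
        coords = rng.normal(size=(200, 4))
        a = two_step_cluster(embedding_from_coords(coords), k_micro=20, seed=3)
        b = two_step_cluster(embedding_from_coords(coords), k_micro=20, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_k_micro_at_least_two_below_n(self, rng):
        coords = rng.normal(size=(10, 2))
        with pytest.raises(ClassificationError):
            two_step_cluster(embedding_from_coords(coords), k_micro=10)
        with pytest.raises(ClassificationError):
            two_step_cluster(embedding_from_coords(coords), k_micro=1)


class TestRankClusterGenes:
    def _matrix(self, rng, n_genes=30, n_cells=40):
        vals = np.abs(rng.normal(1.0, 0.3, size=(n_genes, n_cells)))
        return expression_from_dense(vals)

    def test_exclusive_gene_ranks_first(self, rng):
        x = self._matrix(rng)
        clusters = np.array([1] * 15 + [2] * 25)
        x.x[7, :] = 0.0
        x.x[7, :15] = 3.0  # expressed only inside cluster 1
        ranked = rank_cluster_genes(x, clusters, 1)
        assert ranked.genes[0] == x.genes[7]
        assert ranked.metric[0] > 0

    def test_all_zero_gene_has_zero_log2fc(self, rng):
        x = self._matrix(rng)
        x.x[3, :] = 0.0
        ranked = rank_cluster_genes(x, np.array([1] * 15 + [2] * 25), 1)
        idx = list(ranked.genes).index(x.genes[3])
        assert ranked.metric[idx] == 0.0

    def test_identical_distributions_give_flat_ranking(self):
        """With in/out values identical, log2FC is 0 and the exact rank-sum
        enumeration oracle gives p = 1 for every gene."""
        vals = np.tile(np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0, 1.0, 2.0]), (5, 1))
        x = expression_from_dense(vals)
        clusters = np.array([1, 1, 2, 2, 1, 1, 2, 2])  # both clusters see {1,2,1,2}
        ranked = rank_cluster_genes(x, clusters, 1, min_cells=4)
        np.testing.assert_allclose(ranked.metric, 0.0, atol=1e-12)
        p_oracle = oracles.wilcoxon_exact_two_sided(vals[0, clusters == 1], vals[0, clusters == 2])
        assert p_oracle == 1.0

    def test_small_cluster_rejected(self, rng):
        x = self._matrix(rng)
        with pytest.raises(ClassificationError, match="cells"):
            rank_cluster_genes(x, np.array([1] * 5 + [2] * 35), 1, min_cells=10)

    def test_wilcoxon_tie_break_matches_exact_enumeration(self, rng):
        """The asymptotic rank-sum used for tie-breaking tracks the exact
        enumeration oracle on small distinct samples."""
        import scipy.stats

        a, b = rng.normal(0, 1, 6), rng.normal(1.2, 1, 6)
        p_asym = scipy.stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic"
        ).pvalue
        p_exact = oracles.wilcoxon_exact_two_sided(a, b)
        assert abs(p_asym - p_exact) < 0.08


def ranked_list(metric, genes=None):
    metric = np.asarray(metric, float)
    genes = np.asarray(
        genes if genes is not None else [f"G{i}" for i in range(len(metric))],
        dtype=object,
    )
    order = np.argsort(-metric, kind="stable")
    return RankedList(genes=genes[order], metric=metric[order], cluster_id=0)


class TestGseaES:
    def test_single_top_gene_reaches_one(self):
        r = ranked_list([3.0, 2.0, 1.0, 0.5], genes=["GENE1", "GENE2", "GENE3", "GENE4"])
        es = gsea_es(r, GeneSet("s", ("GENE1",)))
        assert es == pytest.approx(1.0, abs=1e-12)

    def test_bottom_gene_set_negative(self):
        r = ranked_list([3.0, 2.0, 1.0, 0.5], genes=["A", "B", "C", "D"])
        assert gsea_es(r, GeneSet("s", ("D",))) < 0

    def test_brute_force_oracle_equivalence(self, rng):
        """200 random rankings with N <= 8 and exhaustive gene sets."""
        for _ in range(200):
            n = int(rng.integers(3, 9))
            metric = rng.normal(0, 2, size=n)
            genes = np.array([f"G{i}" for i in range(n)], dtype=object)
            r = ranked_list(metric, genes)
            for size in range(1, n):
                for members in itertools.combinations(r.genes, size):
                    gs = GeneSet("s", tuple(members))
                    hit = np.array([g in set(gs.genes) for g in r.genes])
                    expected = oracles.es_brute_force(r.metric, hit)
                    assert gsea_es(r, gs) == pytest.approx(expected, abs=1e-12)

    def test_rescaling_invariance(self, rng):
        metric = rng.normal(0, 1, size=12)
        genes = [f"G{i}" for i in range(12)]
        gs = GeneSet("s", ("G1", "G4", "G9"))
        a = gsea_es(ranked_list(metric, genes), gs)
        b = gsea_es(ranked_list(metric * 7.3, genes), gs)
        assert a == pytest.approx(b, abs=1e-12)

    def test_degenerate_sets_rejected(self):
        r = ranked_list([1.0, 0.5], genes=["A", "B"])
        with pytest.raises(ClassificationError):
            gsea_es(r, GeneSet("s", ("A", "B")))  # empty complement
        with pytest.raises(ClassificationError):
            gsea_es(r, GeneSet("s", ("ZZ",)))  # empty intersection


class TestGseaPermutation:
    def test_planted_signature_significant(self, rng):
        n_genes, n_cells = 300, 60
        vals = np.abs(rng.normal(1, 0.5, size=(n_genes, n_cells)))
        clusters = np.array([1] * 20 + [0] * 40)
        sig = [f"G{i:03d}" for i in range(15)]
        vals[:15, :20] *= 2.0
        x = expression_from_dense(np.log1p(vals))
        # the add-one same-sign p has resolution ~1/(1 + n_same); with 200
        # permutations and an even sign split its floor hovers around 0.01,
        # so the decisive assertion uses 1000 permutations
        res = gsea_permutation(x, clusters, 1, GeneSet("sig", tuple(sig)), n_perm=200, seed=1)
        assert res.p <= 0.02
        assert res.nes > 1.0
        res1k = gsea_permutation(x, clusters, 1, GeneSet("sig", tuple(sig)), n_perm=1000, seed=1)
        assert res1k.p <= 0.01
        assert res1k.nes > 1.0

    def test_exhaustive_enumeration_matches_independent_oracle(self, rng):
        """3-vs-3 cells: the exhaustive mode must reproduce an independent
        enumeration over all 20 label splits."""
        n_genes = 12
        vals = np.abs(rng.normal(1, 0.5, size=(n_genes, 6)))
        x = expression_from_dense(np.log1p(vals))
        clusters = np.array([1, 1, 1, 0, 0, 0])
        members = {"G000", "G001", "G002"}
        res = gsea_permutation(
            x, clusters, 1, GeneSet("s", tuple(members)), exhaustive=True, min_cells=3
        )
        es_all = oracles.enumerate_splits_es(
            np.expm1(x.x), x.genes, members, k=3
        )
        assert len(es_all) == 20
        obs = es_all[0]  # first combination is the observed split (0,1,2)
        same = es_all * np.sign(obs) > 0
        p_oracle = (np.abs(es_all[same]) >= abs(obs) - 1e-12).sum() / same.sum()
        assert res.p == pytest.approx(p_oracle, abs=1e-12)
        assert res.es == pytest.approx(obs, abs=1e-12)

    def test_seed_reproducibility(self, rng):
        vals = np.abs(rng.normal(1, 0.4, size=(50, 40)))
        x = expression_from_dense(np.log1p(vals))
        clusters = np.array([1] * 15 + [0] * 25)
        gs = GeneSet("s", tuple(f"G{i:03d}" for i in range(8)))
        a = gsea_permutation(x, clusters, 1, gs, n_perm=50, seed=9)
        b = gsea_permutation(x, clusters, 1, gs, n_perm=50, seed=9)
        assert (a.p, a.nes) == (b.p, b.nes)

    def test_minimum_permutations_enforced(self, rng):
        vals = np.abs(rng.normal(1, 0.4, size=(20, 30)))
        x = expression_from_dense(vals)
        with pytest.raises(ClassificationError):
            gsea_permutation(
                x, np.array([1] * 10 + [0] * 20), 1,
                GeneSet("s", ("G000",)), n_perm=5,
            )


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(0, 1, size=int(rng.integers(3, 40)))
            ours = benjamini_hochberg(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, theirs, atol=1e-12)


def make_results(cluster_id, nes_p):
    out = []
    for paradigm in CANONICAL_PARADIGMS:
        nes, p_adj = nes_p.get(paradigm, (0.5, 0.9))
        out.append(
            EnrichmentResult(
                cluster_id=cluster_id, paradigm=paradigm, es=np.sign(nes) * 0.5,
                nes=nes, p=p_adj / 2, p_adj=p_adj, n_perm=100,
            )
        )
    return out


class TestAssignParadigms:
    BARCODES = np.array(["b0", "b1", "b2"], dtype=object)

    def test_unique_qualifying_max_wins(self):
        results = {1: make_results(1, {
            "intrinsic_apoptosis": (2.1, 0.01),
            "pyroptosis": (1.2, 0.30),
        })}
        table = assign_paradigms(results, np.array([1, 1, 1]), self.BARCODES)
        assert set(table.cells["paradigm"]) == {"intrinsic_apoptosis"}
        assert set(table.cells["state"]) == {"apoptosis"}

    def test_nothing_enriched_is_healthy(self):
        results = {1: make_results(1, {})}
        table = assign_paradigms(results, np.array([1, 1, 1]), self.BARCODES)
        assert set(table.cells["state"]) == {"healthy"}

    def test_tie_broken_by_canonical_order(self):
        results = {1: make_results(1, {
            "pyroptosis": (1.5, 0.01),
            "ferroptosis": (1.5, 0.01),  # earlier in canonical order
        })}
        table = assign_paradigms(results, np.array([1, 1, 1]), self.BARCODES)
        assert set(table.cells["paradigm"]) == {"ferroptosis"}

    def test_missing_paradigm_result_is_error(self):
        results = {1: make_results(1, {})[:-1]}
        with pytest.raises(ClassificationError, match="missing"):
            assign_paradigms(results, np.array([1, 1, 1]), self.BARCODES)

    def test_negative_nes_never_selected(self):
        results = {1: make_results(1, {"pyroptosis": (-3.0, 0.001)})}
        table = assign_paradigms(results, np.array([1, 1, 1]), self.BARCODES)
        assert set(table.cells["state"]) == {"healthy"}
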