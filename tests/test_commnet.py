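import numpy as np
import pandas as pd
import pytest

from conftest import expression_from_dense
from nkfate.commnet import (
    CommError,
    LRPair,
    _trimean,
    aggregate_pathways,
    detect_overexpressed,
    interaction_probability,
    permutation_significance,
    read_lr_database,
    score_communication,
    trimean_expression,
)


def planted_channel(rng, n_per=40, lig_boost=3.0, rec_boost=3.0):
    """Three populations; LIG high only in 'src', REC high only in 'tgt'."""
    genes = ["LIG", "REC", "HK", "BG1", "BG2"]
    n = 3 * n_per
    vals = np.abs(rng.normal(0.5, 0.15, size=(5, n)))
    vals[2] = 1.0  # housekeeping, flat everywhere
    groups = np.array(["src"] * n_per + ["tgt"] * n_per + ["other"] * n_per)
    vals[0, :n_per] += lig_boost
    vals[1, n_per : 2 * n_per] += rec_boost
    return expression_from_dense(vals, genes=genes), groups


class TestTrimean:
    def test_known_quartile_example(self):
        # type-7 quartiles of {0,0,0,4}: Q1=0, Q2=0, Q3=1 -> trimean 0.25
        assert _trimean(np.array([0.0, 0.0, 0.0, 4.0])) == pytest.approx(0.25)

    def test_constant_is_identity(self):
        assert _trimean(np.full(7, 3.2)) == pytest.approx(3.2)

    def test_all_zero_is_zero(self, rng):
        x, groups = planted_channel(rng)
        x.x[3, :] = 0.0
        assert trimean_expression(x, groups, "src", "BG1") == 0.0


class TestInteractionProbability:
    def test_zero_ligand_gives_zero(self):
        assert interaction_probability(0.0, 5.0) == 0.0

    def test_unit_expression_example(self):
        assert interaction_probability(1.0, 1.0, kh=0.5) == pytest.approx(2.0 / 3.0)

    def test_monotone_in_both_arguments(self):
        grid = np.linspace(0.1, 5, 20)
        probs_l = [interaction_probability(l, 1.0) for l in grid]
        probs_r = [interaction_probability(1.0, r) for r in grid]
        assert np.all(np.diff(probs_l) > 0)
        assert np.all(np.diff(probs_r) > 0)
        assert max(probs_l) < 1.0

    def test_negative_input_rejected(self):
        with pytest.raises(CommError):
            interaction_probability(-0.1, 1.0)


class TestDetectOverexpressed:
    def test_planted_ligand_detected_only_in_source(self, rng):
        x, groups = planted_channel(rng)
        over = detect_overexpressed(x, groups)
        assert "LIG" in over["src"]
        assert "LIG" not in over["tgt"] and "LIG" not in over["other"]

    def test_housekeeping_gene_nowhere(self, rng):
        x, groups = planted_channel(rng)
        over = detect_overexpressed(x, groups)
        assert all("HK" not in s for s in over.values())

    def test_all_zero_gene_nowhere(self, rng):
        x, groups = planted_channel(rng)
        x.x[3, :] = 0.0
        over = detect_overexpressed(x, groups)
        assert all("BG1" not in s for s in over.values())

    def test_small_population_skipped_with_warning(self, rng):
        x, groups = planted_channel(rng, n_per=20)
        groups = groups.copy()
        groups[:5] = "tiny"
        with pytest.warns(UserWarning, match="tiny"):
            over = detect_overexpressed(x, groups)
        assert "tiny" not in over


class TestPermutationSignificance:
    PAIR = LRPair("LIG", ("REC",), "TEST")

    def test_planted_pair_reaches_minimum_p(self, rng):
        x, groups = planted_channel(rng)
        prob, p = permutation_significance(
            x, groups, self.PAIR, "src", "tgt", n_perm=100, seed=0
        )
        assert p == pytest.approx(1.0 / 101.0)
        assert prob > 0.9

    def test_null_channel_rarely_significant(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            vals = np.abs(rng.normal(1.0, 0.3, size=(3, 90)))
            x = expression_from_dense(vals, genes=["LIG", "REC", "BG"])
            groups = np.array(["a"] * 30 + ["b"] * 30 + ["c"] * 30)
            _, p = permutation_significance(
                x, groups, self.PAIR, "a", "b", n_perm=100, seed=seed
            )
            hits += p <= 0.05
        assert hits <= 1

    def test_seed_reproducible(self, rng):
        x, groups = planted_channel(rng)
        r1 = permutation_significance(x, groups, self.PAIR, "src", "tgt", seed=7)
        r2 = permutation_significance(x, groups, self.PAIR, "src", "tgt", seed=7)
        assert r1 == r2

    def test_minimum_permutations(self, rng):
        x, groups = planted_channel(rng)
        with pytest.raises(CommError):
            permutation_significance(x, groups, self.PAIR, "src", "tgt", n_perm=5)


class TestAggregatePathways:
    def _pairs(self, rows):
        return pd.DataFrame(
            rows,
            columns=["ligand", "receptor", "pathway", "source", "target",
                     "probability", "p", "significant"],
        )

    def test_single_pair(self):
        g = aggregate_pathways(
            self._pairs([["L", "R", "PW", "a", "b", 0.5, 0.01, True]])
        )
        assert g.weight("a", "b", "PW") == pytest.approx(0.5)
        assert g.table["n_pairs"].iloc[0] == 1

    def test_same_pathway_weights_add(self):
        g = aggregate_pathways(
            self._pairs(
                [
                    ["L1", "R1", "PW", "a", "b", 0.3, 0.01, True],
                    ["L2", "R2", "PW", "a", "b", 0.4, 0.01, True],
                    ["L3", "R3", "PW", "a", "b", 0.9, 0.50, False],
                ]
            )
        )
        assert g.weight("a", "b", "PW") == pytest.approx(0.7)
        assert g.table["n_pairs"].iloc[0] == 2

    def test_empty_graph_allowed_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            g = aggregate_pathways(
                self._pairs([["L", "R", "PW", "a", "b", 0.5, 0.9, False]])
            )
        assert len(g.table) == 0


class TestScoreCommunication:
    def test_planted_channel_dominates(self, rng):
        x, groups = planted_channel(rng)
        graph = score_communication(
            x, groups, [LRPair("LIG", ("REC",), "TEST")], n_perm=100, seed=0
        )
        assert len(graph.table) >= 1
        totals = graph.table.groupby(["source", "target"])["weight"].sum()
        assert totals.idxmax() == ("src", "tgt")

    def test_no_lr_genes_present_is_error(self, rng):
        x, groups = planted_channel(rng)
        with pytest.raises(CommError):
            score_communication(x, groups, [LRPair("NOPE", ("NADA",), "PW")])


class TestLRDatabase:
    def test_multi_subunit_receptor_parsed(self):
        pair = LRPair("TGFB1", "TGFBR1;TGFBR2", "TGFB")
        assert pair.receptor == ("TGFBR1", "TGFBR2")

    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "lr.tsv"
        p.write_text("ligand\treceptor\tpathway\nL1\tR1;R2\tPW\n")
        pairs = read_lr_database(p)
        assert pairs[0].receptor == ("R1", "R2")

    def test_missing_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("ligand\treceptor\nL1\tR1\n")
        with pytest.raises(CommError):
            read_lr_database(p)

    def test_packaged_database_loads(self):
        from nkfate.commnet import packaged_lr_database

        pairs = packaged_lr_database()
        pathways = {p.pathway for p in pairs}
        assert {"CXCL", "NOTCH", "TGFB", "SELPLG"} <= pathways
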