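import numpy as np
import pytest

import oracles
from nkfate.trajectory import (
    TrajectoryError,
    decision_points,
    fit_mst,
    pseudotime,
)


def cells_at(centroids, labels, n_per=5, noise=0.0, rng=None):
    coords, labs = [], []
    for c, lab in zip(centroids, labels):
        pts = np.tile(np.asarray(c, float), (n_per, 1))
        if noise and rng is not None:
            pts = pts + rng.normal(0, noise, size=pts.shape)
        coords.append(pts)
        labs.extend([lab] * n_per)
    return np.vstack(coords), np.array(labs)


class TestFitMst:
    def test_collinear_centroids_form_a_path(self):
        coords, labels = cells_at([(0, 0), (1, 0), (5, 0)], ["A", "B", "C"])
        model = fit_mst(coords, labels)
        edges = {tuple(sorted(e[:2])) for e in model.edges}
        assert edges == {("A", "B"), ("B", "C")}

    def test_two_groups_single_edge(self):
        coords, labels = cells_at([(0, 0), (3, 4)], ["A", "B"])
        model = fit_mst(coords, labels)
        assert len(model.edges) == 1
        assert model.edges[0][2] == pytest.approx(5.0)

    def test_total_weight_matches_exhaustive_minimum(self, rng):
        """100 random configurations with up to 6 nodes."""
        for _ in range(100):
            k = int(rng.integers(3, 7))
            cents = rng.normal(0, 5, size=(k, 3))
            coords, labels = cells_at(cents, [f"N{i}" for i in range(k)], n_per=1)
            model = fit_mst(coords, labels)
            dist = np.linalg.norm(cents[:, None] - cents[None, :], axis=2)
            expected = oracles.mst_weight_brute_force(dist)
            assert model.total_weight == pytest.approx(expected, abs=1e-9)

    def test_tree_shape_invariants(self, rng):
        cents = rng.normal(size=(6, 2))
        coords, labels = cells_at(cents, list("ABCDEF"))
        model = fit_mst(coords, labels)
        import networkx as nx

        g = model.graph()
        assert g.number_of_edges() == 5
        assert nx.is_connected(g)

    def test_single_group_rejected(self):
        coords, labels = cells_at([(0, 0)], ["A"])
        with pytest.raises(TrajectoryError):
            fit_mst(coords, labels)


class TestPseudotime:
    def test_cell_at_root_centroid_is_zero(self):
        coords, labels = cells_at([(0, 0), (2, 0)], ["root", "leaf"], n_per=3)
        model = fit_mst(coords, labels)
        pt = pseudotime(model, coords, labels, root="root")
        assert pt[0] == pytest.approx(0.0, abs=1e-12)

    def test_midpoint_of_root_edge_is_half_length(self):
        coords = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 0.0]])
        labels = np.array(["root", "leaf", "leaf"])
        model = fit_mst(coords[:2], labels[:2])
        pt = pseudotime(model, coords, labels, root="root")
        assert pt[2] == pytest.approx(1.0)

    def test_linear_differentiation_recovers_depth(self, rng):
        """States strung along a line: pseudotime must track planted depth."""
        import scipy.stats

        depths = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        centroids = np.column_stack([depths * 3.0, np.zeros(5)])
        coords, labels = cells_at(
            centroids, [f"S{int(d)}" for d in depths], n_per=60, noise=0.7, rng=rng
        )
        true_depth = np.repeat(depths, 60) + rng.normal(0, 0.05, 300)
        model = fit_mst(coords, labels)
        pt = pseudotime(model, coords, labels, root="S0")
        rho = scipy.stats.spearmanr(pt, true_depth).statistic
        assert rho >= 0.9

    def test_rigid_rotation_invariance(self, rng):
        cents = rng.normal(0, 4, size=(4, 2))
        coords, labels = cells_at(cents, list("ABCD"), n_per=10, noise=0.3, rng=rng)
        model = fit_mst(coords, labels)
        pt = pseudotime(model, coords, labels, root="A")
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        coords_r = coords @ rot.T
        model_r = fit_mst(coords_r, labels)
        pt_r = pseudotime(model_r, coords_r, labels, root="A")
        np.testing.assert_allclose(pt, pt_r, atol=1e-9)

    def test_rerooting_matches_independent_geodesics(self, rng):
        """Node-level pseudotime after re-rooting equals brute-force
        all-pairs shortest paths on the tree."""
        cents = rng.normal(0, 5, size=(5, 3))
        coords, labels = cells_at(cents, list("ABCDE"), n_per=1)
        model = fit_mst(coords, labels)
        # Floyd-Warshall by hand on the MST edges
        nodes = model.nodes
        n = len(nodes)
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        for a, b, w in model.edges:
            i, j = nodes.index(a), nodes.index(b)
            d[i, j] = d[j, i] = w
        for k in range(n):
            for i in range(n):
                for j in range(n):
                    d[i, j] = min(d[i, j], d[i, k] + d[k, j])
        for root in nodes:
            pt = pseudotime(model, coords, labels, root=root)
            ri = nodes.index(root)
            for idx, lab in enumerate(labels):
                assert pt[idx] == pytest.approx(d[ri, nodes.index(lab)], abs=1e-9)

    def test_unknown_root_rejected(self):
        coords, labels = cells_at([(0, 0), (1, 1)], ["A", "B"])
        model = fit_mst(coords, labels)
        with pytest.raises(TrajectoryError):
            pseudotime(model, coords, labels, root="Z")


class TestDecisionPoints:
    def test_path_has_none(self):
        coords, labels = cells_at([(0, 0), (1, 0), (2, 0), (3, 0)], list("ABCD"))
        model = fit_mst(coords, labels)
        assert decision_points(model) == []

    def test_star_hub_detected(self):
        coords, labels = cells_at(
            [(0, 0), (2, 0), (-2, 0), (0, 2)], ["hub", "L1", "L2", "L3"]
        )
        model = fit_mst(coords, labels)
        assert decision_points(model) == ["hub"]

    def test_ordered_by_pseudotime_when_rooted(self, rng):
        # two hubs at different distances from the root
        centroids = [(0, 0), (2, 0), (2, 2), (2, -2), (5, 0), (7, 2), (7, -2)]
        labels = ["root", "hub1", "a", "b", "hub2", "c", "d"]
        coords, labs = cells_at(centroids, labels)
        model = fit_mst(coords, labs)
        pseudotime(model, coords, labs, root="root")
        assert decision_points(model) == ["hub1", "hub2"]
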