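import numpy as np
import pandas as pd
import pytest

import oracles
from nkfate.coexpnet import (
    CoexpError,
    CoexpParams,
    adjacency,
    adjacency_tom,
    detect_modules,
    loess_trend,
    module_eigengene,
    module_trait_correlation,
    ora,
    pick_soft_threshold,
)
from nkfate.genesets import GeneSet


def two_block_data(rng, n_per_block=50, n_obs=60, within=0.9):
    """Two planted modules driven by independent latent factors."""
    out = []
    for _ in range(2):
        latent = rng.normal(size=n_obs)
        noise_sd = np.sqrt(1.0 / within - 1.0)
        out.append(latent + rng.normal(0, noise_sd, size=(n_per_block, n_obs)))
    return np.vstack(out)


class TestAdjacencyTom:
    def test_perfectly_correlated_triple(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.vstack([base, 2 * base + 1, 0.5 * base])
        t = adjacency_tom(x, CoexpParams(beta=6))
        # all pairwise |cor| = 1: t_ij = (1 + 1) / (2 + 1 - 1) = 1
        np.testing.assert_allclose(t, 1.0, atol=1e-12)

    def test_orthogonal_profiles_have_zero_overlap(self):
        x = np.array(
            [[1.0, -1.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0], [1.0, -1.0, -1.0, 1.0]]
        )
        t = adjacency_tom(x)
        off = t[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_matches_triple_loop_oracle(self, rng):
        x = rng.normal(size=(15, 25))
        t = adjacency_tom(x, CoexpParams(beta=6))
        expected = oracles.tom_brute_force(x, beta=6)
        np.testing.assert_allclose(t, expected, atol=1e-12)

    def test_symmetry_range_and_monotonicity(self, rng):
        x = rng.normal(size=(20, 30))
        t = adjacency_tom(x)
        np.testing.assert_allclose(t, t.T, atol=1e-12)
        assert t.min() >= 0 and t.max() <= 1
        np.testing.assert_allclose(np.diag(t), 1.0)
        # adjacency is monotone in |cor|
        a = adjacency(x, beta=6)
        c = np.abs(np.corrcoef(x))
        iu = np.triu_indices(20, 1)
        order = np.argsort(c[iu])
        assert np.all(np.diff(a[iu][order]) >= -1e-12)

    def test_constant_gene_rejected(self, rng):
        x = rng.normal(size=(5, 10))
        x[2] = 3.0
        with pytest.raises(CoexpError, match="constant"):
            adjacency_tom(x)


class TestPickSoftThreshold:
    def test_hub_structured_data_reaches_scale_free_fit(self, rng):
        # hub-like loadings: r^6 follows a power-law density, giving the
        # heavy-tailed connectivity that scale-free topology requires
        n_obs, n_genes = 80, 300
        u = rng.uniform(0.05, 1, size=n_genes)
        r = np.clip(u ** (1 / 3.0), 0.05, 0.995)
        load = r / np.sqrt(1 - r**2)
        x = load[:, None] * rng.normal(size=n_obs) + rng.normal(0, 1, size=(n_genes, n_obs))
        beta, table = pick_soft_threshold(x, r2_threshold=0.8)
        assert table.loc[table["beta"] == beta, "r2"].iloc[0] >= 0.8

    def test_pure_noise_takes_warning_path(self, rng):
        x = rng.normal(size=(120, 400))
        with pytest.warns(UserWarning, match="argmax"):
            pick_soft_threshold(x, r2_threshold=0.98)

    def test_single_candidate_returned_unconditionally(self, rng):
        x = rng.normal(size=(60, 30))
        beta, _ = pick_soft_threshold(x, candidate_betas=(6,))
        assert beta == 6.0


class TestDetectModules:
    def test_two_planted_blocks_recovered(self, rng):
        x = two_block_data(rng, n_per_block=50, n_obs=60, within=0.9)
        names = [f"A{i}" for i in range(50)] + [f"B{i}" for i in range(50)]
        tom = adjacency_tom(x)
        res = detect_modules(tom, CoexpParams(min_module_size=30), gene_names=names, x=x)
        assert len(res.module_ids) == 2
        for mid in res.module_ids:
            genes = set(res.genes_in(mid))
            jac_a = len(genes & {f"A{i}" for i in range(50)}) / len(
                genes | {f"A{i}" for i in range(50)}
            )
            jac_b = len(genes & {f"B{i}" for i in range(50)}) / len(
                genes | {f"B{i}" for i in range(50)}
            )
            assert max(jac_a, jac_b) >= 0.95

    def test_iid_noise_mostly_unassigned(self, rng):
        x = rng.normal(size=(100, 50))
        tom = adjacency_tom(x)
        res = detect_modules(tom, CoexpParams(min_module_size=10), x=x)
        assert (res.modules == 0).mean() >= 0.8

    def test_oversized_min_module_size_leaves_all_grey(self, rng):
        x = two_block_data(rng, n_per_block=10, n_obs=40)
        tom = adjacency_tom(x)
        with pytest.warns(UserWarning, match="module 0"):
            res = detect_modules(tom, CoexpParams(min_module_size=100), x=x)
        assert set(res.modules) == {0}

    def test_permutation_calibrated_cut_requires_data(self, rng):
        x = rng.normal(size=(40, 30))
        tom = adjacency_tom(x)
        with pytest.raises(CoexpError, match="calibration"):
            detect_modules(tom, CoexpParams(cut_height=None))


class TestModuleEigengene:
    def test_identical_genes_explain_everything(self, rng):
        profile = rng.normal(size=30)
        x = np.tile(profile, (8, 1))
        e, share = module_eigengene(x)
        assert share == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        corr = np.corrcoef(e, z)[0, 1]
        assert corr == pytest.approx(1.0)

    def test_orientation_invariant_to_global_sign_flip(self, rng):
        x = rng.normal(size=(10, 25)) + rng.normal(size=25)
        e1, _ = module_eigengene(x)
        e2, _ = module_eigengene(-x)
        # orientation rule re-aligns with the module mean profile
        assert abs(np.corrcoef(e1, -e2)[0, 1]) == pytest.approx(1.0)
        assert np.dot(e1, x.mean(axis=0) - x.mean()) >= 0

    def test_planted_factor_recovered(self, rng):
        latent = rng.normal(size=40)
        x = latent + rng.normal(0, 0.3, size=(20, 40))
        e, share = module_eigengene(x)
        assert abs(np.corrcoef(e, latent)[0, 1]) >= 0.95

    def test_rank_zero_module_rejected(self):
        with pytest.raises(CoexpError):
            module_eigengene(np.ones((3, 10)))


class TestModuleTraitCorrelation:
    def test_monotone_transform_has_rho_one(self):
        trait = np.linspace(0, 1, 20)
        eig = pd.DataFrame({"M1": np.exp(3 * trait)})
        out = module_trait_correlation(eig, trait)
        assert out.loc["M1", "rho"] == pytest.approx(1.0)
        assert out.loc["M1", "p"] == 0.0

    def test_student_t_p_value_formula(self, rng):
        import scipy.stats

        eig = pd.DataFrame({"M1": rng.normal(size=15)})
        trait = rng.normal(size=15)
        out = module_trait_correlation(eig, trait)
        rho = out.loc["M1", "rho"]
        t = rho * np.sqrt(13 / (1 - rho**2))
        assert out.loc["M1", "p"] == pytest.approx(2 * scipy.stats.t.sf(abs(t), 13))

    def test_permuted_trait_mostly_null(self, rng):
        hits = 0
        for _ in range(100):
            eig = pd.DataFrame({"M1": rng.normal(size=20)})
            out = module_trait_correlation(eig, rng.normal(size=20))
            hits += out.loc["M1", "p"] > 0.05
        assert hits >= 85

    def test_minimum_observations(self):
        eig = pd.DataFrame({"M1": [0.1, 0.2, 0.3]})
        with pytest.raises(CoexpError):
            module_trait_correlation(eig, np.array([1.0, 2.0, 3.0]))


class TestOra:
    def test_exact_tail_sum_oracle(self):
        """k=5 of a 10-gene set, 20-gene list, 100-gene universe."""
        universe = [f"U{i:03d}" for i in range(100)]
        gene_set = GeneSet("s", tuple(universe[:10]))
        gene_list = universe[5:10] + universe[50:65]  # overlap exactly 5
        out = ora(gene_list, gene_set, universe)
        expected = oracles.hypergeom_upper_tail(5, 10, 100, 20)
        assert out.loc["s", "overlap"] == 5
        assert out.loc["s", "p"] == pytest.approx(expected, rel=1e-12)

    def test_disjoint_list_p_one(self):
        universe = [f"U{i:03d}" for i in range(50)]
        out = ora(universe[30:40], GeneSet("s", tuple(universe[:10])), universe)
        assert out.loc["s", "p"] == pytest.approx(1.0)

    def test_list_equal_set_is_minimal_p(self):
        universe = [f"U{i:03d}" for i in range(60)]
        sets = [GeneSet("exact", tuple(universe[:10])), GeneSet("other", tuple(universe[20:40]))]
        out = ora(universe[:10], sets, universe)
        assert out["p"].idxmin() == "exact"
        assert out.loc["exact", "p"] == pytest.approx(
            oracles.hypergeom_upper_tail(10, 10, 60, 10), rel=1e-12
        )

    def test_empty_list_rejected(self):
        with pytest.raises(CoexpError):
            ora([], GeneSet("s", ("A", "B", "C", "D", "E")), ["A", "B", "C", "D", "E"])


class TestLoessTrend:
    def test_linear_data_reproduced(self, rng):
        x = np.linspace(0, 10, 40)
        y = 2.0 * x + 1.0
        out = loess_trend(x, y, seed=0)
        inner = out.iloc[5:-5]
        np.testing.assert_allclose(inner["fit"], 2.0 * inner.index.to_numpy() + 1.0, atol=1e-6)

    def test_plateau_flattens_late_slope(self, rng):
        x = np.linspace(0, 10, 120)
        y = 3.0 * (1 - np.exp(-x)) + rng.normal(0, 0.02, size=120)
        out = loess_trend(x, y, span=0.4, seed=0)
        xs = out.index.to_numpy()
        fit = out["fit"].to_numpy()
        lo = xs <= np.quantile(xs, 1 / 3)
        hi = xs >= np.quantile(xs, 2 / 3)
        slope_lo = np.polyfit(xs[lo], fit[lo], 1)[0]
        slope_hi = np.polyfit(xs[hi], fit[hi], 1)[0]
        assert abs(slope_hi) < 0.1 * abs(slope_lo)

    def test_duplicate_x_handled(self, rng):
        x = np.repeat(np.arange(10.0), 3)
        y = x + rng.normal(0, 0.1, size=30)
        out = loess_trend(x, y, seed=1)
        assert len(out) == 10
        assert np.all(out["hi"] >= out["lo"])

    def test_too_few_points_rejected(self):
        with pytest.raises(CoexpError):
            loess_trend(np.arange(5.0), np.arange(5.0))
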