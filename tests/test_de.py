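import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import nichecomm as nc
from nichecomm.errors import DegenerateInputError


class TestDepthQuartiles:
    def test_equal_split_in_depth_order(self):
        np.testing.assert_array_equal(
            nc.depth_quartiles(np.arange(1, 9)), [1, 1, 2, 2, 3, 3, 4, 4]
        )

    def test_remainder_goes_to_earliest_rank_blocks(self):
        strata = nc.depth_quartiles(np.arange(9))
        sizes = [int((strata == s).sum()) for s in (1, 2, 3, 4)]
        assert sizes == [3, 2, 2, 2]

    def test_tied_depths_split_by_stable_input_order(self):
        depths = np.ones(8)
        first = nc.depth_quartiles(depths)
        second = nc.depth_quartiles(depths)
        np.testing.assert_array_equal(first, [1, 1, 2, 2, 3, 3, 4, 4])
        np.testing.assert_array_equal(first, second)

    def test_too_few_cells_rejected(self):
        with pytest.raises(DegenerateInputError):
            nc.depth_quartiles(np.array([5, 6, 7]))

    def test_strata_partition_cells_regardless_of_order(self):
        rng = np.random.default_rng(0)
        depths = rng.integers(100, 10_000, size=37)
        strata = nc.depth_quartiles(depths)
        sizes = np.bincount(strata)[1:]
        assert sizes.sum() == 37 and sizes.max() - sizes.min() <= 1
        # block s holds depth ranks below block s+1
        order = np.argsort(depths, kind="stable")
        assert (np.diff(strata[order]) >= 0).all()


class TestWilcoxonZ:
    def test_separated_groups_give_known_z(self):
        assert nc.wilcoxon_z([4, 5, 6], [1, 2, 3]) == pytest.approx(1.964, abs=1e-3)

    def test_identical_multisets_give_zero(self):
        assert nc.wilcoxon_z([1, 2, 2, 5], [2, 5, 1, 2]) == 0.0

    def test_antisymmetry_under_group_swap(self):
        assert nc.wilcoxon_z([1, 2, 3], [4, 5, 6]) == pytest.approx(-1.964, abs=1e-3)
        rng = np.random.default_rng(5)
        x, y = rng.poisson(2, 20), rng.poisson(2, 30)
        assert nc.wilcoxon_z(x, y) == pytest.approx(-nc.wilcoxon_z(y, x))

    def test_matches_scipy_normal_approximation_with_ties(self):
        """Tie-corrected Z must reproduce scipy's asymptotic Mann-Whitney p."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.poisson(1.5, size=rng.integers(5, 40))
            y = rng.poisson(2.0, size=rng.integers(5, 40))
            z = nc.wilcoxon_z(x, y)
            p_ours = 2 * stats.norm.sf(abs(z))
            p_scipy = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=False
            ).pvalue
            assert p_ours == pytest.approx(p_scipy, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            nc.wilcoxon_z([], [1, 2])


class TestCombineZ:
    def test_equal_scores_equal_weights(self):
        assert nc.combine_z([2, 2, 2, 2]) == pytest.approx(4.0)

    def test_all_zero(self):
        assert nc.combine_z([0, 0, 0, 0]) == 0.0

    def test_mixed_signs_unweighted(self):
        assert nc.combine_z([1, -1, 2, 0], [1, 1, 1, 1]) == pytest.approx(1.0)

    def test_single_stratum_reduces_to_its_z(self):
        assert nc.combine_z([1.7], [3.0]) == pytest.approx(1.7)

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=6),
        st.floats(0.1, 10),
    )
    def test_rescaling_weights_leaves_combination_unchanged(self, zs, factor):
        w = [1.0] * len(zs)
        scaled = [factor] * len(zs)
        assert nc.combine_z(zs, w) == pytest.approx(nc.combine_z(zs, scaled), abs=1e-9)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(DegenerateInputError):
            nc.combine_z([1.0], [0.0])


class TestStratifiedDE:
    def _planted_dataset(self, seed=0):
        # 4 clusters of 200 -> the planted comparison is 200 in-group vs 600 out-group
        cfg = nc.SimConfig(
            n_clusters=4,
            cells_per_cluster=200,
            n_genes=200,
            markers=(nc.MarkerSpec("G001", "C1", 4.0),),
            n_decoys=0,
            seed=seed,
        )
        adata, _, _ = nc.simulate_dataset(cfg)
        norm = nc.normalize_counts(adata)
        strata = nc.depth_quartiles(nc.total_counts(adata))
        return adata, norm, strata

    def test_planted_fourfold_marker_passes_paper_thresholds(self):
        adata, norm, strata = self._planted_dataset(seed=21)
        de = nc.stratified_de(norm, adata.obs["cluster"], "C1", strata=strata, genes=adata.var_names)
        row = de.set_index("gene").loc["G001"]
        assert row["q_value"] < 0.005
        assert row["log2_fc"] > 0.02
        assert row["n_in"] == 200 and row["n_out"] == 600

    def test_null_genes_have_nominal_type_i_error(self):
        cfg = nc.SimConfig(n_clusters=2, cells_per_cluster=150, n_genes=1000, n_decoys=0, seed=9)
        adata, _, _ = nc.simulate_dataset(cfg)
        norm = nc.normalize_counts(adata)
        strata = nc.depth_quartiles(nc.total_counts(adata))
        de = nc.stratified_de(norm, adata.obs["cluster"], "C1", strata=strata)
        fpr = (de["p_value"] < 0.05).mean()
        assert 0.03 <= fpr <= 0.07

    def test_constant_gene_yields_z_zero_q_one(self):
        norm = np.ones((8, 1))
        de = nc.stratified_de(norm, list("AAAABBBB"), "A", strata=None)
        assert de.loc[0, "z_combined"] == 0.0
        assert de.loc[0, "q_value"] == pytest.approx(1.0)

    def test_swapping_groups_negates_combined_z(self):
        rng = np.random.default_rng(2)
        norm = rng.poisson(2.0, size=(40, 15)).astype(float)
        clusters = np.array(["A"] * 18 + ["B"] * 22)
        strata = nc.depth_quartiles(norm.sum(axis=1))
        za = nc.stratified_de(norm, clusters, "A", strata=strata)["z_combined"]
        zb = nc.stratified_de(norm, clusters, "B", strata=strata)["z_combined"]
        np.testing.assert_allclose(za, -zb, atol=1e-12)

    def test_bh_q_values_monotone_in_p_rank(self):
        adata, norm, strata = self._planted_dataset(seed=5)
        de = nc.stratified_de(norm, adata.obs["cluster"], "C1", strata=strata)
        de = de.sort_values("p_value")
        assert (np.diff(de["q_value"]) >= -1e-12).all()
        assert ((de["q_value"] >= de["p_value"] - 1e-12)).all()

    def test_unweighted_mode_matches_manual_stouffer(self):
        rng = np.random.default_rng(8)
        norm = rng.poisson(3.0, size=(24, 5)).astype(float)
        clusters = np.array(["A", "B", "B"] * 8)
        strata = np.repeat([1, 2, 3, 4], 6)
        de_u = nc.stratified_de(norm, clusters, "A", strata=strata, weighting="unweighted")
        zs = []
        for s in (1, 2, 3, 4):
            block = strata == s
            z_gene = [
                nc.wilcoxon_z(
                    norm[block & (clusters == "A"), j], norm[block & (clusters == "B"), j]
                )
                for j in range(5)
            ]
            zs.append(z_gene)
        manual = [nc.combine_z([zs[s][j] for s in range(4)]) for j in range(5)]
        np.testing.assert_allclose(de_u["z_combined"], manual, atol=1e-12)

    def test_absent_cluster_is_a_key_error(self):
        with pytest.raises(KeyError):
            nc.stratified_de(np.ones((8, 2)), list("AAAABBBB"), "Z", strata=None)
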