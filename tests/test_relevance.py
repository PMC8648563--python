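import pandas as pd
import pytest

import nichecomm as nc
from nichecomm.errors import ConfigError

from _oracle import (
    random_relevance_fixture,
    relevant_set_from_oracle,
    relevant_set_from_package,
)


class TestThresholds:
    def test_defaults_follow_main_text(self):
        t = nc.RelevanceThresholds()
        assert (t.min_frac, t.min_log2_fc, t.max_fdr) == (0.10, 0.02, 0.005)

    def test_supplementary_preset_positive_lfc_stricter_fdr(self):
        t = nc.RelevanceThresholds.preset("supplementary")
        assert t.min_log2_fc == 0.0 and t.max_fdr == 0.001

    @pytest.mark.parametrize("kwargs", [{"min_frac": -0.1}, {"max_fdr": 0.0}, {"max_fdr": 1.0}])
    def test_invalid_thresholds_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            nc.RelevanceThresholds(**kwargs)


class TestIsExpressed:
    def test_ten_percent_boundary_is_inclusive(self, toy_summary, wnt_db):
        assert nc.is_expressed("JAG1", "A", toy_summary, 0.10, wnt_db)  # frac exactly 0.10

    def test_just_below_boundary_fails(self, toy_summary, wnt_db):
        assert not nc.is_expressed("NOTCH2", "A", toy_summary, 0.10, wnt_db)  # frac 0.099

    def test_complex_limited_by_weakest_subunit(self, toy_summary, wnt_db):
        # FZD5 at 0.5 but LRP6 at 0.05 -> the heteromer is not expressed
        assert not nc.is_expressed("WNT_receptor", "A", toy_summary, 0.10, wnt_db)


def _null_de(clusters, genes):
    rows = [(c, g, 0.0, 1.0, 1.0, 0.0, 1, 1) for c in clusters for g in genes]
    return pd.DataFrame(
        rows, columns=["cluster", "gene", "z_combined", "p_value", "q_value", "log2_fc", "n_in", "n_out"]
    )


class TestCallInteractions:
    def test_zero_expression_matrix_yields_no_relevant_records(self, wnt_db):
        genes = wnt_db.genes
        zero = pd.DataFrame(0.0, index=["A", "B"], columns=genes)
        summary = nc.ClusterExpressionSummary(zero, zero.copy(), pd.Series({"A": 5, "B": 5}))
        pairs = nc.eligible_pairs(
            nc.MicroenvironmentSet([nc.Microenvironment("e", ("A", "B"))])
        )
        de = _null_de(["A", "B"], genes)
        de.loc[:, "q_value"] = 0.0  # even perfect DE cannot rescue criterion 1
        de.loc[:, "log2_fc"] = 1.0
        rel = nc.call_interactions(summary, de, pairs, wnt_db)
        assert not rel["relevant"].any()

    def test_planted_pair_is_called_with_its_ligand_as_de_member(self):
        planted = nc.PlantedInteraction("G001", "G002", "C1", "C2", fold=4.0)
        cfg = nc.SimConfig(
            n_clusters=3, cells_per_cluster=200, n_genes=150,
            interactions=(planted,), n_decoys=0, seed=33,
        )
        adata, db, _ = nc.simulate_dataset(cfg)
        envs = nc.MicroenvironmentSet([nc.Microenvironment("shared", ("C1", "C2"))])
        res = nc.run_stages(adata, db, envs)
        rel = res["relevance"]
        row = rel[
            (rel.interaction_id == "I001") & (rel.cluster_a == "C1") & (rel.cluster_b == "C2")
        ].iloc[0]
        assert row["relevant"]
        assert "G001@C1" in row["de_members"]

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        thresholds = nc.RelevanceThresholds()
        for seed in range(5):
            adata, db, envs, _ = random_relevance_fixture(seed)
            results = nc.run_stages(adata, db, envs, thresholds=thresholds)
            ours = relevant_set_from_package(results)
            oracle = relevant_set_from_oracle(adata, db, envs, results["de"], thresholds)
            assert ours == oracle

    def test_tightening_thresholds_never_adds_relevant_records(self):
        adata, db, envs, _ = random_relevance_fixture(101)
        res = nc.run_stages(adata, db, envs)
        base = res["relevance"]["relevant"].sum()
        for tighter in (
            nc.RelevanceThresholds(min_frac=0.3),
            nc.RelevanceThresholds(max_fdr=0.0005),
            nc.RelevanceThresholds(min_log2_fc=0.5),
        ):
            rel = nc.call_interactions(res["summary"], res["de"], res["pairs"], db, tighter)
            assert rel["relevant"].sum() <= base

    def test_no_relevant_record_outside_eligible_pairs(self):
        adata, db, envs, _ = random_relevance_fixture(55)
        res = nc.run_stages(adata, db, envs)
        eligible = set(
            zip(res["pairs"].cluster_a, res["pairs"].cluster_b, res["pairs"].microenvironment)
        )
        hits = res["relevance"][res["relevance"]["relevant"]]
        emitted = set(zip(hits.cluster_a, hits.cluster_b, hits.microenvironment))
        assert emitted <= eligible

    def test_identical_partners_make_relevance_orientation_symmetric(self, toy_summary):
        db = nc.InteractionDatabase(
            genes=["WNT7A", "FZD5", "LRP6", "JAG1", "NOTCH2", "DKK1"],
            interactions=pd.DataFrame(
                [("I1", "FZD5", "FZD5", "homotypic")],
                columns=["interaction_id", "partner_a", "partner_b", "annotation"],
            ),
        )
        pairs = nc.eligible_pairs(
            nc.MicroenvironmentSet([nc.Microenvironment("e", ("A", "B"))])
        )
        de = _null_de(["A", "B"], db.genes)
        de.loc[(de.cluster == "A") & (de.gene == "FZD5"), ["q_value", "log2_fc"]] = [1e-4, 1.0]
        rel = nc.call_interactions(toy_summary, de, pairs, db).set_index(["cluster_a", "cluster_b"])
        assert rel.loc[("A", "B"), "relevant"] == rel.loc[("B", "A"), "relevant"]

    def test_interaction_with_missing_gene_is_skipped_with_warning(self, toy_summary, wnt_db):
        slim = nc.ClusterExpressionSummary(
            toy_summary.mean_expr.drop(columns=["LRP6"]),
            toy_summary.frac_expr.drop(columns=["LRP6"]),
            toy_summary.n_cells,
        )
        pairs = nc.eligible_pairs(
            nc.MicroenvironmentSet([nc.Microenvironment("e", ("A", "B"))])
        )
        rel = nc.call_interactions(slim, _null_de(["A", "B"], slim.genes), pairs, wnt_db)
        assert set(rel["interaction_id"]) == {"I2"}
        assert any("LRP6" in msg for msg in rel.attrs["skipped"])

    def test_unknown_cluster_in_pairs_is_a_key_error(self, toy_summary, wnt_db):
        pairs = pd.DataFrame(
            [("A", "Z", "e")], columns=["cluster_a", "cluster_b", "microenvironment"]
        )
        with pytest.raises(KeyError):
            nc.call_interactions(toy_summary, _null_de(["A", "B"], wnt_db.genes), pairs, wnt_db)


class TestBinaryMatrix:
    def _pairs(self):
        return nc.eligible_pairs(
            nc.MicroenvironmentSet([nc.Microenvironment("e", ("A", "B"))])
        )

    def test_empty_relevance_gives_all_zero_matrix_with_full_frame(self, toy_summary, wnt_db):
        rel = nc.call_interactions(
            toy_summary, _null_de(["A", "B"], wnt_db.genes), self._pairs(), wnt_db
        )
        mat = nc.to_binary_matrix(rel, self._pairs())
        assert (mat.to_numpy() == 0).all()
        assert mat.shape == (2, 3)  # 2 interactions x {AA, AB(=BA), BB}

    def test_one_relevant_record_sets_exactly_one_entry(self, toy_summary, wnt_db):
        de = _null_de(["A", "B"], wnt_db.genes)
        de.loc[(de.cluster == "B") & (de.gene == "NOTCH2"), ["q_value", "log2_fc"]] = [1e-4, 1.0]
        rel = nc.call_interactions(toy_summary, de, self._pairs(), wnt_db)
        mat = nc.to_binary_matrix(rel, self._pairs())
        assert int(mat.to_numpy().sum()) == 1
        assert mat.loc["I2", "e|A|B"] == 1

    def test_matrix_sum_counts_relevant_interaction_pair_combinations(self):
        adata, db, envs, _ = random_relevance_fixture(77)
        res = nc.run_stages(adata, db, envs)
        hits = res["relevance"][res["relevance"]["relevant"]]
        combos = {
            (iid, env, tuple(sorted((a, b))))
            for iid, env, a, b in zip(
                hits.interaction_id, hits.microenvironment, hits.cluster_a, hits.cluster_b
            )
        }
        mat = nc.to_binary_matrix(res["relevance"], res["pairs"])
        assert int(mat.to_numpy().sum()) == len(combos)
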