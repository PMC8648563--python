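"""Label-permutation null for interaction scores.

Plants one strong ligand-receptor pair between two co-occurring clusters and
compares its Monte-Carlo p-value (add-one estimator over 1000 cluster-label
shuffles) with the p-values of unplanted decoy interactions.
"""

import nichecomm as nc

planted = nc.PlantedInteraction("G01", "G02", source="C1", target="C2", fold=8.0)
cfg = nc.SimConfig(n_clusters=2, cells_per_cluster=150, n_genes=60,
                   baseline_mean=1.0, interactions=(planted,),
                   n_decoys=10, seed=4)
adata, db, truth = nc.simulate_dataset(cfg)

envs = nc.MicroenvironmentSet([nc.Microenvironment("shared", ("C1", "C2"))])
pairs = nc.eligible_pairs(envs, ["C1", "C2"])
tab = nc.permutation_pvalues(
    nc.normalize_counts(adata), adata.obs["cluster"], list(adata.var_names),
    db, pairs, nc.PermutationConfig(n_permutations=1000, seed=9),
)

planted_row = tab.query("interaction_id == 'I001' and cluster_a == 'C1' and cluster_b == 'C2'")
print(f"planted pair score={planted_row.score.iloc[0]:.2f} "
      f"p={planted_row.p_value.iloc[0]:.6f}  (floor is 1/1001 = {1/1001:.6f})")
decoys = tab[tab.interaction_id.str.startswith("D")]
print(f"decoy p-values: median={decoys.p_value.median():.3f}, "
      f"min={decoys.p_value.min():.3f} over {len(decoys)} rows")
print()
print("The planted pair's observed score beats all 1000 label shuffles, so its")
print("p-value sits at the add-one floor; decoys are indistinguishable from null.")
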