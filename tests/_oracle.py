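"""Independent brute-force implementation of the two relevance criteria.

Everything here is plain-Python double loops over cells, genes, interactions
and cluster pairs, deliberately sharing no code path with the package's
vectorized implementation.  It consumes raw counts and a plain-dict copy of
the database, and applies verbatim:

1. every member gene of each partner expressed (raw count > 0) in at least
   ``min_frac`` of the assigned cluster's cells, and
2. at least one member gene differentially expressed (q < max_fdr and
   log2 fold change > min_log2_fc) in either cluster of the pair.
"""

from __future__ import annotations


def brute_force_relevance(
    counts,  # list-of-lists or 2D array of raw counts, cells x genes
    cell_clusters,  # per-cell cluster label
    genes,  # gene names matching columns
    complexes: dict,  # complex_id -> subunit list
    interactions,  # iterable of (interaction_id, partner_a, partner_b)
    env_members: dict,  # env name -> list of cluster labels
    de_map: dict,  # (cluster, gene) -> (q_value, log2_fc)
    min_frac: float,
    min_log2_fc: float,
    max_fdr: float,
) -> set:
    """Set of relevant (interaction_id, cluster_a, cluster_b, env) tuples."""
    gene_col = {g: j for j, g in enumerate(genes)}
    clusters = sorted(set(map(str, cell_clusters)))

    frac = {}
    for c in clusters:
        rows = [i for i, lab in enumerate(cell_clusters) if str(lab) == c]
        for g in genes:
            j = gene_col[g]
            expressing = 0
            for i in rows:
                if counts[i][j] > 0:
                    expressing += 1
            frac[(c, g)] = expressing / len(rows)

    def members(pid):
        return list(complexes[pid]) if pid in complexes else [pid]

    relevant = set()
    for env, env_clusters in env_members.items():
        present = [c for c in env_clusters if c in clusters]
        for ca in present:
            for cb in present:
                for iid, pa, pb in interactions:
                    ok = True
                    for g in members(pa):
                        if g not in gene_col or frac[(ca, g)] < min_frac:
                            ok = False
                    for g in members(pb):
                        if g not in gene_col or frac[(cb, g)] < min_frac:
                            ok = False
                    if not ok:
                        continue
                    de_hit = False
                    for g in members(pa) + members(pb):
                        for c in (ca, cb):
                            q_lfc = de_map.get((c, g))
                            if q_lfc is not None:
                                q, lfc = q_lfc
                                if q < max_fdr and lfc > min_log2_fc:
                                    de_hit = True
                    if de_hit:
                        relevant.add((iid, ca, cb, env))
    return relevant


# ---------------------------------------------------------------------------
# Shared fixture machinery for oracle-equivalence checks.  Fixture generation
# may use the package's simulator (it only builds inputs); the checking path
# above never touches package code.

import numpy as np

import nichecomm as nc


def random_relevance_fixture(seed: int):
    """Random small dataset + database (with heteromers) + two environments."""
    rng = np.random.default_rng(seed)
    n_clusters = int(rng.integers(3, 7))
    n_genes = int(rng.integers(120, 301))
    clusters = [f"C{i + 1}" for i in range(n_clusters)]
    width = len(str(n_genes))
    gene = lambda i: f"G{i:0{width}d}"

    n_planted = int(rng.integers(2, 6))
    planted = []
    gi = 1
    for k in range(n_planted):
        lig = gene(gi); gi += 1
        if k == 0:  # one heteromeric (2-subunit) receptor per fixture
            rec = (gene(gi), gene(gi + 1)); gi += 2
        else:
            rec = gene(gi); gi += 1
        src, tgt = rng.choice(clusters, size=2, replace=True)
        planted.append(nc.PlantedInteraction(lig, rec, str(src), str(tgt), fold=4.0))
    markers = tuple(
        nc.MarkerSpec(gene(gi + j), str(rng.choice(clusters)), fold=float(rng.uniform(2, 5)))
        for j in range(int(rng.integers(0, 4)))
    )
    cfg = nc.SimConfig(
        n_clusters=n_clusters,
        cells_per_cluster=30,
        n_genes=n_genes,
        markers=markers,
        interactions=tuple(planted),
        n_decoys=int(rng.integers(3, 30 - len(planted))),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    adata, db, truth = nc.simulate_dataset(cfg)

    def env_members():
        size = int(rng.integers(2, n_clusters + 1))
        return tuple(str(c) for c in rng.choice(clusters, size=size, replace=False))

    envs = nc.MicroenvironmentSet(
        [nc.Microenvironment("env1", env_members()), nc.Microenvironment("env2", env_members())]
    )
    return adata, db, envs, truth


def relevant_set_from_package(results) -> set:
    rel = results["relevance"]
    hits = rel[rel["relevant"]]
    return set(
        zip(hits["interaction_id"], hits["cluster_a"], hits["cluster_b"], hits["microenvironment"])
    )


def relevant_set_from_oracle(adata, db, envs, de_table, thresholds) -> set:
    counts = np.asarray(adata.X)
    de_map = {
        (str(c), str(g)): (q, f)
        for c, g, q, f in zip(
            de_table["cluster"], de_table["gene"], de_table["q_value"], de_table["log2_fc"]
        )
    }
    return brute_force_relevance(
        counts=counts.tolist(),
        cell_clusters=list(adata.obs["cluster"].astype(str)),
        genes=list(adata.var_names),
        complexes={k: list(v) for k, v in db.complexes.items()},
        interactions=[
            (r["interaction_id"], r["partner_a"], r["partner_b"])
            for _, r in db.interactions.iterrows()
        ],
        env_members={e.name: list(e.members) for e in envs},
        de_map=de_map,
        min_frac=thresholds.min_frac,
        min_log2_fc=thresholds.min_log2_fc,
        max_fdr=thresholds.max_fdr,
    )
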