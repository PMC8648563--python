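"""Clustered negative-binomial count simulator with planted markers and
ligand-receptor pairs.

The generator emulates the statistical structure the relevance pipeline
assumes in droplet single-cell data: gene-wise negative-binomial counts
(variance m + alpha m^2), heterogeneous per-cell library sizes (log-normal
factors with unit mean, optionally multiplied by a per-cluster depth factor to
create sequencing-depth confounds), cluster-specific planted marker genes, and
planted ligand-receptor pairs whose ligand members are raised in a source
cluster and receptor members in a target cluster.  A matching interaction
database containing the planted interactions (including multi-subunit
complexes) plus baseline decoy interactions is emitted alongside ground truth,
all driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData

from .database import InteractionDatabase
from .errors import ConfigError


@dataclass(frozen=True)
class MarkerSpec:
    """Multiply ``gene``'s negative-binomial mean by ``fold`` in ``cluster``."""

    gene: str
    cluster: str
    fold: float = 4.0


@dataclass(frozen=True)
class PlantedInteraction:
    """Ligand members raised ``fold``-fold in ``source``, receptor members in ``target``.

    ``ligand``/``receptor`` are a gene name or a tuple of gene names (the
    latter becomes a heteromeric complex in the emitted database).
    """

    ligand: str | tuple[str, ...]
    receptor: str | tuple[str, ...]
    source: str
    target: str
    fold: float = 4.0

    @property
    def ligand_members(self) -> tuple[str, ...]:
        return (self.ligand,) if isinstance(self.ligand, str) else tuple(self.ligand)

    @property
    def receptor_members(self) -> tuple[str, ...]:
        return (self.receptor,) if isinstance(self.receptor, str) else tuple(self.receptor)


@dataclass(frozen=True)
class SimConfig:
    n_clusters: int = 4
    cells_per_cluster: int = 200
    n_genes: int = 500
    baseline_mean: float = 0.5  # NB mean counts per gene before library scaling
    dispersion: float = 0.5  # alpha in var = m + alpha m^2
    libsize_sigma: float = 0.6  # log-normal sigma of per-cell factors (unit mean)
    depth_multipliers: tuple[float, ...] | None = None  # per cluster, default all 1
    markers: tuple[MarkerSpec, ...] = ()
    interactions: tuple[PlantedInteraction, ...] = ()
    decoys_per_planted: int = 5
    n_decoys: int | None = None  # overrides the per-planted ratio when set
    n_donors: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clusters, self.cells_per_cluster, self.n_genes, self.n_donors) <= 0:
            raise ConfigError("all sizes must be positive")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if any(m.fold <= 0 for m in self.markers) or any(
            i.fold <= 0 for i in self.interactions
        ):
            raise ConfigError("fold-changes must be positive")
        if self.depth_multipliers is not None and len(self.depth_multipliers) != self.n_clusters:
            raise ConfigError("depth_multipliers must have one entry per cluster")

    @property
    def cluster_names(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_clusters)]

    @property
    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Planted structure: marker table and interaction table (planted + decoys)."""

    markers: pd.DataFrame  # gene, cluster, fold
    interactions: pd.DataFrame  # interaction_id, ligand, receptor, source, target, fold, planted


def _fold_matrix(cfg: SimConfig) -> np.ndarray:
    clusters = cfg.cluster_names
    genes = {g: j for j, g in enumerate(cfg.gene_names)}
    cl = {c: i for i, c in enumerate(clusters)}
    fold = np.ones((cfg.n_clusters, cfg.n_genes))
    for m in cfg.markers:
        if m.gene not in genes or m.cluster not in cl:
            raise ConfigError(f"marker references unknown gene/cluster: {m}")
        fold[cl[m.cluster], genes[m.gene]] *= m.fold
    for it in cfg.interactions:
        for side, cluster in ((it.ligand_members, it.source), (it.receptor_members, it.target)):
            if cluster not in cl or any(g not in genes for g in side):
                raise ConfigError(f"planted interaction references unknown gene/cluster: {it}")
            for g in side:
                fold[cl[cluster], genes[g]] *= it.fold
    return fold


def _build_database(cfg: SimConfig, rng: np.random.Generator) -> tuple[InteractionDatabase, pd.DataFrame]:
    complexes: dict[str, list[str]] = {}
    rows = []

    def partner_id(members: tuple[str, ...]) -> str:
        if len(members) == 1:
            return members[0]
        cid = "CPX_" + "_".join(members)
        complexes[cid] = list(members)
        return cid

    used_genes: set[str] = set()
    for k, it in enumerate(cfg.interactions, start=1):
        used_genes.update(it.ligand_members + it.receptor_members)
        rows.append(
            {
                "interaction_id": f"I{k:03d}",
                "partner_a": partner_id(it.ligand_members),
                "partner_b": partner_id(it.receptor_members),
                "annotation": "planted",
                "ligand": "+".join(it.ligand_members),
                "receptor": "+".join(it.receptor_members),
                "source": it.source,
                "target": it.target,
                "fold": it.fold,
                "planted": True,
            }
        )
    used_genes.update(m.gene for m in cfg.markers)

    n_decoys = (
        cfg.n_decoys
        if cfg.n_decoys is not None
        else cfg.decoys_per_planted * len(cfg.interactions)
    )
    free = [g for g in cfg.gene_names if g not in used_genes]
    if n_decoys > len(free) // 2:
        raise ConfigError("not enough unplanted genes to draw decoy interactions from")
    picked = rng.choice(len(free), size=2 * n_decoys, replace=False)
    for k in range(n_decoys):
        lig, rec = free[picked[2 * k]], free[picked[2 * k + 1]]
        rows.append(
            {
                "interaction_id": f"D{k + 1:03d}",
                "partner_a": lig,
                "partner_b": rec,
                "annotation": "decoy",
                "ligand": lig,
                "receptor": rec,
                "source": "",
                "target": "",
                "fold": 1.0,
                "planted": False,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "interaction_id", "partner_a", "partner_b", "annotation",
            "ligand", "receptor", "source", "target", "fold", "planted",
        ],
    )
    db = InteractionDatabase(
        genes=cfg.gene_names,
        complexes=complexes,
        interactions=truth[["interaction_id", "partner_a", "partner_b", "annotation"]].copy(),
        version="synthetic",
    )
    return db, truth


def simulate_dataset(cfg: SimConfig) -> tuple[AnnData, InteractionDatabase, GroundTruth]:
    """Draw a seeded clustered count matrix with its database and ground truth.

    Counts for cell c (cluster k) and gene g are negative binomial with mean
    ``baseline_mean * fold[k, g] * lib_c`` where ``lib_c`` is a unit-mean
    log-normal library factor times the cluster's depth multiplier, and
    variance ``m + dispersion * m^2`` (gamma-Poisson draw).
    """
    rng = np.random.default_rng(cfg.seed)
    n_cells = cfg.n_clusters * cfg.cells_per_cluster
    cluster_of = np.repeat(np.arange(cfg.n_clusters), cfg.cells_per_cluster)
    depth = (
        np.ones(cfg.n_clusters)
        if cfg.depth_multipliers is None
        else np.asarray(cfg.depth_multipliers, dtype=float)
    )
    # unit-mean log-normal library factors: E[exp(N(-s^2/2, s^2))] = 1
    lib = rng.lognormal(-cfg.libsize_sigma**2 / 2.0, cfg.libsize_sigma, size=n_cells)
    lib *= depth[cluster_of]

    fold = _fold_matrix(cfg)
    mean = cfg.baseline_mean * fold[cluster_of] * lib[:, None]
    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape, mean / shape)
    counts = rng.poisson(lam).astype(np.int64)

    names = cfg.cluster_names
    obs = pd.DataFrame(
        {
            "cluster": pd.Categorical([names[i] for i in cluster_of], categories=names),
            "donor": [f"donor{(i % cfg.n_donors) + 1}" for i in range(n_cells)],
        },
        index=[f"cell{i + 1:05d}" for i in range(n_cells)],
    )
    adata = AnnData(X=counts, obs=obs, var=pd.DataFrame(index=cfg.gene_names))
    adata.obs["total_counts"] = counts.sum(axis=1)

    db, truth = _build_database(cfg, rng)
    markers = pd.DataFrame(
        [(m.gene, m.cluster, m.fold) for m in cfg.markers],
        columns=["gene", "cluster", "fold"],
    )
    return adata, db, GroundTruth(markers=markers, interactions=truth)


def depth_confounded_null(
    depth_ratio: float = 2.0,
    cells_per_cluster: int = 300,
    n_genes: int = 2000,
    seed: int = 0,
    **overrides,
) -> tuple[AnnData, InteractionDatabase, GroundTruth]:
    """Two clusters from one expression model with unequal sequencing depth.

    This is the failure mode depth stratification corrects: a naive rank test
    on these data inflates false positives, the stratified test should not.
    """
    cfg = SimConfig(
        n_clusters=2,
        cells_per_cluster=cells_per_cluster,
        n_genes=n_genes,
        depth_multipliers=(1.0, depth_ratio),
        markers=(),
        interactions=(),
        n_decoys=0,
        seed=seed,
        **overrides,
    )
    return simulate_dataset(cfg)
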