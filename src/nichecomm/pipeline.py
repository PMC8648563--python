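"""End-to-end run: summarize -> stratified DE -> eligible pairs -> relevance
calls (-> optional permutation null), with a JSON run manifest."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from anndata import AnnData

from . import __version__
from .database import InteractionDatabase, load_database
from .de import de_all_clusters
from .errors import ConfigError
from .expression import normalize_counts, summarize_clusters, total_counts
from .io import (
    attach_annotation,
    read_annotation,
    read_counts_mtx,
    read_counts_tsv,
    sha256_digest,
    write_manifest,
    write_table,
)
from .microenv import MicroenvironmentSet, eligible_pairs, load_microenvironments
from .permutation import PermutationConfig, permutation_pvalues
from .relevance import RelevanceThresholds, call_interactions, to_binary_matrix

logger = logging.getLogger("nichecomm")


@dataclass
class RunConfig:
    counts: str  # MTX path or dense TSV path
    annotation: str
    gene_table: str
    complex_table: str
    interaction_table: str
    microenvironments: str
    outdir: str
    genes_file: str | None = None  # required with an MTX counts file
    barcodes_file: str | None = None
    orientation: str = "cells-by-genes"
    scale: float = 10_000.0
    thresholds: RelevanceThresholds = field(default_factory=RelevanceThresholds)
    weighting: str = "sqrt_n"
    n_strata: int = 4
    run_permutation: bool = False
    n_permutations: int = 1000
    seed: int = 0
    log_level: str = "INFO"


def _load_counts(cfg: RunConfig) -> AnnData:
    if str(cfg.counts).endswith(".mtx"):
        if not (cfg.genes_file and cfg.barcodes_file):
            raise ConfigError("MTX input needs genes_file and barcodes_file")
        return read_counts_mtx(cfg.counts, cfg.genes_file, cfg.barcodes_file, cfg.orientation)
    return read_counts_tsv(cfg.counts, cfg.orientation)


def run_stages(
    adata: AnnData,
    db: InteractionDatabase,
    envs: MicroenvironmentSet,
    thresholds: RelevanceThresholds = RelevanceThresholds(),
    scale: float = 10_000.0,
    weighting: str = "sqrt_n",
    n_strata: int = 4,
    run_permutation: bool = False,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """In-memory pipeline over an annotated AnnData; returns all result tables."""
    logger.info("[summarize] normalizing %d cells x %d genes", *adata.shape)
    norm = normalize_counts(adata, scale=scale)
    summary = summarize_clusters(norm, adata)
    logger.info("[de] stratified one-vs-rest over %d clusters", len(summary.clusters))
    de = de_all_clusters(
        norm,
        adata.obs["cluster"],
        total_counts(adata),
        genes=adata.var_names,
        n_strata=n_strata,
        weighting=weighting,
    )
    pairs = eligible_pairs(envs, summary.clusters)
    logger.info("[call] %d eligible ordered pairs", len(pairs))
    relevance = call_interactions(summary, de, pairs, db, thresholds)
    binary = to_binary_matrix(relevance, pairs)
    out = {
        "summary": summary,
        "de": de,
        "pairs": pairs,
        "relevance": relevance,
        "binary": binary,
    }
    if run_permutation:
        logger.info("[permtest] %d permutations", n_permutations)
        out["permutation"] = permutation_pvalues(
            norm,
            adata.obs["cluster"],
            list(adata.var_names),
            db,
            pairs,
            PermutationConfig(n_permutations=n_permutations, seed=seed),
        )
    return out


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """File-to-file pipeline; writes DE table, long relevance table, binary
    matrix, optional permutation table, and a manifest with input digests."""
    logging.basicConfig(level=cfg.log_level, format="%(name)s %(levelname)s %(message)s")
    adata = _load_counts(cfg)
    adata = attach_annotation(adata, read_annotation(cfg.annotation))
    db = load_database(cfg.gene_table, cfg.complex_table, cfg.interaction_table)
    envs = load_microenvironments(cfg.microenvironments)

    results = run_stages(
        adata,
        db,
        envs,
        thresholds=cfg.thresholds,
        scale=cfg.scale,
        weighting=cfg.weighting,
        n_strata=cfg.n_strata,
        run_permutation=cfg.run_permutation,
        n_permutations=cfg.n_permutations,
        seed=cfg.seed,
    )

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "de": write_table(results["de"], outdir / "de_table.tsv"),
        "relevance": write_table(results["relevance"], outdir / "relevance_long.tsv"),
        "binary": write_table(results["binary"], outdir / "binary_matrix.tsv", index=True),
    }
    if "permutation" in results:
        paths["permutation"] = write_table(results["permutation"], outdir / "permutation.tsv")

    input_paths = [
        cfg.counts, cfg.annotation, cfg.gene_table, cfg.complex_table,
        cfg.interaction_table, cfg.microenvironments,
    ] + [p for p in (cfg.genes_file, cfg.barcodes_file) if p]
    manifest = {
        "package_version": __version__,
        "database_version": db.version,
        "seed": cfg.seed,
        "scale": cfg.scale,
        "weighting": cfg.weighting,
        "n_strata": cfg.n_strata,
        "thresholds": asdict(cfg.thresholds),
        "run_permutation": cfg.run_permutation,
        "n_permutations": cfg.n_permutations,
        "input_digests": {str(p): sha256_digest(p) for p in input_paths},
        "skipped_interactions": results["relevance"].attrs.get("skipped", []),
        "warnings": results["summary"].warnings + envs.warnings,
    }
    paths["manifest"] = write_manifest(outdir / "manifest.json", manifest)
    return paths
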