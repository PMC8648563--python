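"""Per-cell library-size normalization and per-cluster expression summaries.

The relevance criteria operate on two per-(cluster, gene) quantities:

* ``mean_expr`` — arithmetic mean of library-normalized (counts-per-``scale``)
  expression, non-log;
* ``frac_expr`` — fraction of the cluster's cells with raw count > 0, the
  quantity thresholded at 10%.

Heteromeric complexes are reduced to the limiting subunit: both statistics are
the minimum over subunits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .database import InteractionDatabase, PartnerRef, members_of
from .errors import DegenerateInputError, MissingGeneError


def _dense_counts(adata: AnnData) -> np.ndarray:
    X = adata.X
    if sparse.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


def total_counts(adata: AnnData) -> np.ndarray:
    """Per-cell sequencing depth (sum of raw counts)."""
    X = adata.X
    if sparse.issparse(X):
        return np.asarray(X.sum(axis=1)).ravel()
    return np.asarray(X).sum(axis=1)


def normalize_counts(adata: AnnData, scale: float = 10_000.0) -> np.ndarray:
    """Scale each cell so its values sum to ``scale`` (counts-per-10k by default).

    Returns a dense cells x genes float matrix; zero entries stay zero.
    Raises DegenerateInputError naming the first cell with zero total count.
    """
    if scale <= 0:
        raise DegenerateInputError(f"scale must be positive, got {scale}")
    counts = _dense_counts(adata)
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        name = adata.obs_names[zero[0]]
        raise DegenerateInputError(f"cell {name!r} has zero total count")
    return counts * (scale / totals)[:, None]


@dataclass
class ClusterExpressionSummary:
    """Per-(cluster, gene) mean normalized expression and fraction expressing."""

    mean_expr: pd.DataFrame  # clusters x genes
    frac_expr: pd.DataFrame  # clusters x genes, values in [0, 1]
    n_cells: pd.Series  # cells per cluster
    warnings: list[str] = field(default_factory=list)

    @property
    def clusters(self) -> list[str]:
        return list(self.mean_expr.index)

    @property
    def genes(self) -> list[str]:
        return list(self.mean_expr.columns)


def summarize_clusters(
    norm_matrix: np.ndarray,
    adata: AnnData,
    cluster_key: str = "cluster",
) -> ClusterExpressionSummary:
    """Summarize normalized expression per cluster.

    ``frac_expr`` is computed from the raw counts in ``adata.X`` (cell is
    "expressing" iff raw count > 0); ``mean_expr`` from ``norm_matrix``.
    Clusters with zero cells (unused categorical levels) are omitted with a
    warning record.
    """
    clusters = pd.Series(adata.obs[cluster_key], index=adata.obs_names).astype(str)
    counts = _dense_counts(adata)
    norm_matrix = np.asarray(norm_matrix, dtype=float)
    if norm_matrix.shape != counts.shape:
        raise DegenerateInputError(
            f"normalized matrix shape {norm_matrix.shape} does not match counts {counts.shape}"
        )
    warnings: list[str] = []
    labels = pd.unique(clusters)
    declared = getattr(adata.obs[cluster_key], "cat", None)
    if declared is not None:
        for lvl in declared.categories:
            if str(lvl) not in set(labels):
                warnings.append(f"cluster {lvl!r} has 0 cells; omitted from summary")
    means, fracs, sizes = {}, {}, {}
    for label in labels:
        mask = (clusters == label).to_numpy()
        n = int(mask.sum())
        sizes[label] = n
        means[label] = norm_matrix[mask].mean(axis=0)
        fracs[label] = (counts[mask] > 0).mean(axis=0)
    genes = list(adata.var_names)
    return ClusterExpressionSummary(
        mean_expr=pd.DataFrame(means, index=genes).T,
        frac_expr=pd.DataFrame(fracs, index=genes).T,
        n_cells=pd.Series(sizes, dtype=int),
        warnings=warnings,
    )


def partner_summary(
    summary: ClusterExpressionSummary,
    partner: PartnerRef | str,
    cluster: str,
    db: InteractionDatabase,
) -> tuple[float, float]:
    """(mean_expr, frac_expr) of a partner in a cluster; complexes via the min rule."""
    genes = members_of(partner, db)
    missing = [g for g in genes if g not in summary.mean_expr.columns]
    if missing:
        raise MissingGeneError(f"gene(s) absent from expression summary: {missing}")
    if cluster not in summary.mean_expr.index:
        raise KeyError(f"cluster {cluster!r} not summarized")
    mean = float(summary.mean_expr.loc[cluster, genes].min())
    frac = float(summary.frac_expr.loc[cluster, genes].min())
    return mean, frac
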