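"""Label-permutation null for interaction scores, restricted to eligible pairs.

The score of an interaction for an ordered cluster pair is the arithmetic mean
of the two partner means (complex partners reduced to their limiting subunit):

    score = (mean_a(partner_a) + mean_b(partner_b)) / 2.

Cluster labels are shuffled uniformly across all analyzed cells; the
Monte-Carlo p-value uses the add-one estimator

    p = (1 + #{null score >= observed}) / (n_permutations + 1),

bounded below by 1/(n+1), so p is never zero.  Only microenvironment-eligible
pairs are scored when the restriction is on (the default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .database import InteractionDatabase, members_of
from .errors import ConfigError, DegenerateInputError

PERM_COLUMNS = [
    "interaction_id",
    "cluster_a",
    "cluster_b",
    "microenvironment",
    "score",
    "p_value",
]


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 1000
    seed: int = 0
    restrict_to_envs: bool = True
    min_frac: float | None = None  # mask scores when either partner is below this fraction

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")


def interaction_score(
    summary, interaction_id: str, cluster_a: str, cluster_b: str, db: InteractionDatabase
) -> float:
    """Mean of the two partner means; complex means via the min rule."""
    from .expression import partner_summary

    inter = db.interaction(interaction_id)
    mean_a, _ = partner_summary(summary, inter["partner_a"], cluster_a, db)
    mean_b, _ = partner_summary(summary, inter["partner_b"], cluster_b, db)
    return (mean_a + mean_b) / 2.0


def _partner_member_index(db: InteractionDatabase, gene_index: dict[str, int]):
    """Per interaction: padded subunit index arrays for each side, or None if a
    member gene is absent from the matrix."""
    a_idx, b_idx, kept, skipped = [], [], [], []
    for _, inter in db.interactions.iterrows():
        ma = members_of(inter["partner_a"], db)
        mb = members_of(inter["partner_b"], db)
        if any(g not in gene_index for g in ma + mb):
            skipped.append(inter["interaction_id"])
            continue
        kept.append(inter["interaction_id"])
        a_idx.append([gene_index[g] for g in ma])
        b_idx.append([gene_index[g] for g in mb])
    width = max((len(x) for x in a_idx + b_idx), default=1)
    pad = lambda idx: np.array([x + [x[0]] * (width - len(x)) for x in idx], dtype=int)
    return kept, pad(a_idx), pad(b_idx), skipped


def permutation_pvalues(
    norm_matrix: np.ndarray,
    clusters,
    genes,
    db: InteractionDatabase,
    pairs: pd.DataFrame,
    cfg: PermutationConfig = PermutationConfig(),
    frac_matrix: np.ndarray | None = None,
) -> pd.DataFrame:
    """Permutation p-values for every interaction x eligible ordered pair.

    ``pairs`` must come from :func:`nichecomm.microenv.eligible_pairs` when
    ``cfg.restrict_to_envs`` is set (the default), so no cross-environment pair
    is ever scored.  Same seed, same table, bit for bit.
    """
    X = np.asarray(norm_matrix, dtype=float)
    labels = np.asarray(clusters).astype(str)
    uniq = pd.unique(labels)
    if uniq.size < 2:
        raise DegenerateInputError("permutation test needs at least 2 clusters")
    if not cfg.restrict_to_envs:
        rows = [(a, b, "") for a in uniq for b in uniq]
        pairs = pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "microenvironment"])

    cluster_index = {c: i for i, c in enumerate(uniq)}
    gene_index = {g: i for i, g in enumerate(genes)}
    if len(gene_index) != X.shape[1]:
        raise DegenerateInputError("gene names do not match matrix columns")
    kept, a_idx, b_idx, skipped = _partner_member_index(db, gene_index)
    if not kept:
        out = pd.DataFrame(columns=PERM_COLUMNS)
        out.attrs["skipped"] = skipped
        return out

    # fixed k x n averaging operator for the observed labels; permuting cells
    # then reduces to applying it to a row-permuted matrix
    n = X.shape[0]
    k = uniq.size
    G = np.zeros((k, n))
    for c, i in cluster_index.items():
        mask = labels == c
        G[i, mask] = 1.0 / mask.sum()

    def partner_minima(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # M: k x genes cluster means -> (k x interactions) min over subunits per side
        return M[:, a_idx].min(axis=2), M[:, b_idx].min(axis=2)

    M_obs = G @ X
    A_obs, B_obs = partner_minima(M_obs)
    pa_s = pairs["cluster_a"].astype(str).map(cluster_index)
    pb_s = pairs["cluster_b"].astype(str).map(cluster_index)
    if pa_s.isna().any() or pb_s.isna().any():
        raise KeyError("pair table references a cluster absent from the labels")
    pa = pa_s.to_numpy(dtype=int)
    pb = pb_s.to_numpy(dtype=int)
    obs = 0.5 * (A_obs[pa] + B_obs[pb])  # pairs x interactions

    rng = np.random.default_rng(cfg.seed)
    exceed = np.zeros_like(obs, dtype=int)
    for _ in range(cfg.n_permutations):
        perm = rng.permutation(n)
        M = G @ X[perm]
        A, B = partner_minima(M)
        null = 0.5 * (A[pa] + B[pb])
        exceed += null >= obs
    pvals = (1.0 + exceed) / (cfg.n_permutations + 1.0)

    if cfg.min_frac is not None:
        if frac_matrix is None:
            raise ConfigError("min_frac masking requires frac_matrix (clusters x genes)")
        F = np.asarray(frac_matrix, dtype=float)
        FA, FB = F[:, a_idx].min(axis=2), F[:, b_idx].min(axis=2)
        mask = (FA[pa] < cfg.min_frac) | (FB[pb] < cfg.min_frac)
        pvals = np.where(mask, 1.0, pvals)

    recs = []
    for j, iid in enumerate(kept):
        for i in range(len(pairs)):
            recs.append(
                (
                    iid,
                    pairs.iloc[i]["cluster_a"],
                    pairs.iloc[i]["cluster_b"],
                    pairs.iloc[i]["microenvironment"],
                    obs[i, j],
                    pvals[i, j],
                )
            )
    out = pd.DataFrame(recs, columns=PERM_COLUMNS)
    out.attrs["skipped"] = skipped
    return out
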