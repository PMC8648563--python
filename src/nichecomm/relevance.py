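"""Relevance calling: the two-criteria decision per interaction and cluster pair.

An interaction is *relevant* for an ordered cluster pair (A, B) inside a shared
microenvironment iff

1. every member gene of the partner assigned to A is expressed in at least
   ``min_frac`` (default 10%) of A's cells, and likewise for B; and
2. at least one member gene of either partner is differentially expressed in A
   or B (one-vs-rest, q < ``max_fdr`` with log2 fold change > ``min_log2_fc``).

Both thresholds printed by the method's source pipelines are exposed as named
presets: the main-text pair (lfc > 0.02, FDR < 0.005, the default) and the
supplementary-table variant (positive lfc, FDR < 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .database import InteractionDatabase, members_of
from .expression import ClusterExpressionSummary, partner_summary
from .errors import ConfigError

RELEVANCE_COLUMNS = [
    "interaction_id",
    "cluster_a",
    "cluster_b",
    "microenvironment",
    "orientation",
    "frac_a",
    "frac_b",
    "mean_a",
    "mean_b",
    "de_members",
    "relevant",
]


@dataclass(frozen=True)
class RelevanceThresholds:
    """Expression and DE cut-offs for the relevance decision."""

    min_frac: float = 0.10
    min_log2_fc: float = 0.02
    max_fdr: float = 0.005

    def __post_init__(self) -> None:
        if not 0 <= self.min_frac <= 1:
            raise ConfigError(f"min_frac must be in [0, 1], got {self.min_frac}")
        if not 0 < self.max_fdr < 1:
            raise ConfigError(f"max_fdr must be in (0, 1), got {self.max_fdr}")

    @classmethod
    def preset(cls, name: str) -> "RelevanceThresholds":
        """``"main"``: lfc > 0.02, FDR < 0.005; ``"supplementary"``: positive lfc, FDR < 0.001."""
        if name == "main":
            return cls()
        if name == "supplementary":
            return cls(min_log2_fc=0.0, max_fdr=0.001)
        raise ConfigError(f"unknown threshold preset: {name!r}")


def is_expressed(
    partner,
    cluster: str,
    summary: ClusterExpressionSummary,
    min_frac: float,
    db: InteractionDatabase,
) -> bool:
    """True iff every member gene's frac_expr in the cluster is >= min_frac (inclusive)."""
    _, frac = partner_summary(summary, partner, cluster, db)
    return bool(frac >= min_frac)


def _de_lookup(de: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float]]:
    return {
        (str(c), str(g)): (q, f)
        for c, g, q, f in zip(de["cluster"], de["gene"], de["q_value"], de["log2_fc"])
    }


def call_interactions(
    summary: ClusterExpressionSummary,
    de: pd.DataFrame,
    pairs: pd.DataFrame,
    db: InteractionDatabase,
    thresholds: RelevanceThresholds = RelevanceThresholds(),
) -> pd.DataFrame:
    """Apply the two relevance criteria to every interaction x eligible pair.

    ``pairs`` is the ordered-pair table from :func:`nichecomm.microenv.eligible_pairs`;
    partner_a is assigned to cluster_a and partner_b to cluster_b for each row
    (the reverse assignment is covered by the reversed ordered pair).
    Interactions with member genes absent from the summary are skipped with a
    warning attached to the returned frame (``.attrs["skipped"]``).
    """
    known_clusters = set(summary.clusters)
    for col in ("cluster_a", "cluster_b"):
        unknown = set(pairs[col].astype(str)) - known_clusters
        if unknown:
            raise KeyError(f"pair table references unknown cluster(s): {sorted(unknown)}")
    de_covered = set(de["cluster"].astype(str))
    needed = set(pairs["cluster_a"].astype(str)) | set(pairs["cluster_b"].astype(str))
    if needed - de_covered:
        raise KeyError(f"DE table missing cluster(s): {sorted(needed - de_covered)}")

    de_map = _de_lookup(de)
    genes_present = set(summary.genes)
    skipped: list[str] = []
    rows = []
    stats_cache: dict[tuple[str, str], tuple[float, float]] = {}

    def partner_stats(partner_id: str, cluster: str) -> tuple[float, float]:
        key = (partner_id, cluster)
        if key not in stats_cache:
            stats_cache[key] = partner_summary(summary, partner_id, cluster, db)
        return stats_cache[key]
    for _, inter in db.interactions.iterrows():
        iid = inter["interaction_id"]
        members_a = members_of(inter["partner_a"], db)
        members_b = members_of(inter["partner_b"], db)
        missing = [g for g in members_a + members_b if g not in genes_present]
        if missing:
            skipped.append(f"interaction {iid!r}: gene(s) {missing} absent from matrix")
            continue
        all_members = list(dict.fromkeys(members_a + members_b))
        for _, pr in pairs.iterrows():
            ca, cb, env = str(pr["cluster_a"]), str(pr["cluster_b"]), pr["microenvironment"]
            mean_a, frac_a = partner_stats(inter["partner_a"], ca)
            mean_b, frac_b = partner_stats(inter["partner_b"], cb)
            expressed = frac_a >= thresholds.min_frac and frac_b >= thresholds.min_frac
            de_members = []
            for g in all_members:
                for c in dict.fromkeys((ca, cb)):
                    hit = de_map.get((c, g))
                    if hit is None:
                        continue
                    q, lfc = hit
                    if q < thresholds.max_fdr and lfc > thresholds.min_log2_fc:
                        de_members.append((g, c))
            rows.append(
                {
                    "interaction_id": iid,
                    "cluster_a": ca,
                    "cluster_b": cb,
                    "microenvironment": env,
                    "orientation": "a|b",
                    "frac_a": frac_a,
                    "frac_b": frac_b,
                    "mean_a": mean_a,
                    "mean_b": mean_b,
                    "de_members": ";".join(f"{g}@{c}" for g, c in de_members),
                    "relevant": bool(expressed and de_members),
                }
            )
    out = pd.DataFrame(rows, columns=RELEVANCE_COLUMNS)
    out.attrs["skipped"] = skipped
    return out


def to_binary_matrix(relevance: pd.DataFrame, pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Binary interactions x (environment, cluster pair) matrix.

    Rows are interaction ids; columns are ``env|clusterA|clusterB`` with the
    cluster pair in canonical (sorted) order; an entry is 1 iff any orientation
    of that unordered pair is relevant.  ``pairs`` (the eligible-pair table)
    fixes the full column frame so an all-negative run still yields a complete
    all-zero matrix.
    """
    def col_key(env, a, b):
        lo, hi = sorted((str(a), str(b)))
        return f"{env}|{lo}|{hi}"

    frame = relevance if pairs is None else pairs
    columns = list(
        dict.fromkeys(
            col_key(e, a, b)
            for e, a, b in zip(
                frame["microenvironment"], frame["cluster_a"], frame["cluster_b"]
            )
        )
    )
    index = list(dict.fromkeys(relevance["interaction_id"]))
    mat = pd.DataFrame(0, index=pd.Index(index, name="interaction_id"), columns=columns, dtype=int)
    hits = relevance[relevance["relevant"]]
    for _, row in hits.iterrows():
        mat.loc[
            row["interaction_id"],
            col_key(row["microenvironment"], row["cluster_a"], row["cluster_b"]),
        ] = 1
    return mat
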