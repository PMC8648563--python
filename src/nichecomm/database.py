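"""Ligand-receptor interaction database: genes, heteromeric complexes, interactions.

An interaction partner is either a single gene product ("simple") or a
heteromeric complex of two or more subunits, referenced through a shared id
namespace: complex ids must not collide with gene ids.  Gene identity is exact
string match against the expression matrix gene names — no symbol aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import CurationError, IntegrityError, PartnerLookupError, SchemaError

INTERACTION_COLUMNS = ["interaction_id", "partner_a", "partner_b", "annotation"]


@dataclass(frozen=True)
class PartnerRef:
    """Uniform reference to either side of an interaction."""

    kind: str  # "simple" | "complex"
    id: str


@dataclass
class InteractionDatabase:
    """Validated gene / complex / interaction tables.

    genes
        Ordered list of gene ids, matching expression-matrix gene names exactly.
    complexes
        Mapping complex_id -> ordered subunit gene list (length >= 2).
    interactions
        DataFrame with columns interaction_id, partner_a, partner_b, annotation.
    """

    genes: list[str]
    complexes: dict[str, list[str]] = field(default_factory=dict)
    interactions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=INTERACTION_COLUMNS)
    )
    version: str = "0"

    def __post_init__(self) -> None:
        self.validate()

    # -- queries ---------------------------------------------------------

    def partner(self, partner_id: str) -> PartnerRef:
        """Resolve an id to a PartnerRef, complex namespace first."""
        if partner_id in self.complexes:
            return PartnerRef("complex", partner_id)
        if partner_id in self._gene_set:
            return PartnerRef("simple", partner_id)
        raise PartnerLookupError(f"unknown partner id: {partner_id!r}")

    def interaction(self, interaction_id: str) -> pd.Series:
        rows = self.interactions[self.interactions["interaction_id"] == interaction_id]
        if rows.empty:
            raise PartnerLookupError(f"unknown interaction id: {interaction_id!r}")
        return rows.iloc[0]

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        genes = list(self.genes)
        if not genes:
            raise IntegrityError("gene table is empty")
        if any(not g for g in genes):
            raise IntegrityError("gene table contains empty gene_id")
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise IntegrityError(f"duplicate gene_id entries: {dupes}")
        self._gene_set = set(genes)

        clash = sorted(self._gene_set & set(self.complexes))
        if clash:
            raise IntegrityError(f"complex ids collide with gene ids: {clash}")
        bad: list[str] = []
        for cid, subunits in self.complexes.items():
            if len(subunits) < 2:
                raise IntegrityError(f"complex {cid!r} has fewer than 2 subunits")
            if len(set(subunits)) != len(subunits):
                raise IntegrityError(f"complex {cid!r} lists a subunit twice")
            if any(s not in self._gene_set for s in subunits):
                bad.append(cid)
        if bad:
            missing = sorted(
                {s for c in bad for s in self.complexes[c] if s not in self._gene_set}
            )
            raise IntegrityError(
                f"complexes {bad} reference genes absent from the gene table: {missing}"
            )

        missing_cols = [c for c in INTERACTION_COLUMNS if c not in self.interactions.columns]
        if missing_cols:
            raise SchemaError(f"interaction table missing column(s): {missing_cols}")
        ids = self.interactions["interaction_id"].tolist()
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate interaction_id entries: {dupes}")
        seen_pairs: dict[frozenset, str] = {}
        for _, row in self.interactions.iterrows():
            self.partner(row["partner_a"])
            self.partner(row["partner_b"])
            key = frozenset((row["partner_a"], row["partner_b"]))
            if key in seen_pairs:
                raise IntegrityError(
                    f"interactions {seen_pairs[key]!r} and {row['interaction_id']!r} "
                    "share the same partner pair (up to orientation)"
                )
            seen_pairs[key] = row["interaction_id"]


def members_of(partner: PartnerRef | str, db: InteractionDatabase) -> list[str]:
    """Ordered member gene list of a partner: [gene] for simple, subunits for complex."""
    ref = partner if isinstance(partner, PartnerRef) else db.partner(partner)
    if ref.kind == "complex":
        if ref.id not in db.complexes:
            raise PartnerLookupError(f"unknown complex id: {ref.id!r}")
        return list(db.complexes[ref.id])
    if ref.id not in set(db.genes):
        raise PartnerLookupError(f"unknown gene id: {ref.id!r}")
    return [ref.id]


def _parse_complex_frame(frame: pd.DataFrame) -> dict[str, list[str]]:
    if "complex_id" not in frame.columns:
        raise SchemaError("complex table missing column(s): ['complex_id']")
    subunit_cols = [c for c in frame.columns if c.startswith("subunit_")]
    if not subunit_cols:
        raise SchemaError("complex table has no subunit_N columns")
    subunit_cols.sort(key=lambda c: int(c.split("_")[1]))
    complexes: dict[str, list[str]] = {}
    for _, row in frame.iterrows():
        subunits = [
            str(row[c]).strip()
            for c in subunit_cols
            if pd.notna(row[c]) and str(row[c]).strip()
        ]
        complexes[str(row["complex_id"])] = subunits
    return complexes


def load_database(
    gene_table_path,
    complex_table_path,
    interaction_table_path,
    version: str = "0",
) -> InteractionDatabase:
    """Load and validate the three CSV tables (comma-separated, header row)."""
    genes_df = pd.read_csv(gene_table_path, dtype=str)
    if "gene_id" not in genes_df.columns:
        raise SchemaError("gene table missing column(s): ['gene_id']")
    complexes_df = pd.read_csv(complex_table_path, dtype=str)
    complexes = _parse_complex_frame(complexes_df) if len(complexes_df) else {}
    if not len(complexes_df) and "complex_id" not in complexes_df.columns:
        raise SchemaError("complex table missing column(s): ['complex_id']")
    inter_df = pd.read_csv(interaction_table_path, dtype=str)
    missing = [c for c in INTERACTION_COLUMNS if c not in inter_df.columns]
    if missing:
        raise SchemaError(f"interaction table missing column(s): {missing}")
    inter_df = inter_df[INTERACTION_COLUMNS].fillna({"annotation": ""})
    return InteractionDatabase(
        genes=genes_df["gene_id"].tolist(),
        complexes=complexes,
        interactions=inter_df.reset_index(drop=True),
        version=version,
    )


def write_database(db: InteractionDatabase, gene_path, complex_path, interaction_path) -> None:
    """Write the three CSV tables in the dialect load_database reads (round-trips)."""
    pd.DataFrame({"gene_id": db.genes}).to_csv(gene_path, index=False)
    max_n = max((len(s) for s in db.complexes.values()), default=2)
    cols = ["complex_id"] + [f"subunit_{i + 1}" for i in range(max_n)]
    rows = []
    for cid, subunits in db.complexes.items():
        rows.append([cid] + subunits + [""] * (max_n - len(subunits)))
    pd.DataFrame(rows, columns=cols).to_csv(complex_path, index=False)
    db.interactions.to_csv(interaction_path, index=False)


def apply_curation(db: InteractionDatabase, curation_table: pd.DataFrame) -> InteractionDatabase:
    """Apply add/replace/remove actions from a curation table, row order, later rows win.

    The table uses the complex-table schema (if it has a ``complex_id`` column)
    or the interaction-table schema (``interaction_id``), plus an ``action``
    column.  Returns a new validated database; the input is not mutated.
    """
    if "action" not in curation_table.columns:
        raise SchemaError("curation table missing column(s): ['action']")
    complexes = {k: list(v) for k, v in db.complexes.items()}
    interactions = db.interactions.copy()

    is_complex = "complex_id" in curation_table.columns
    is_interaction = "interaction_id" in curation_table.columns
    if is_complex == is_interaction:
        raise SchemaError(
            "curation table must carry exactly one of 'complex_id' or 'interaction_id'"
        )

    for _, row in curation_table.iterrows():
        action = str(row["action"]).strip().lower()
        if action not in {"add", "replace", "remove"}:
            raise CurationError(f"unknown curation action: {action!r}")
        if is_complex:
            cid = str(row["complex_id"])
            if action == "add" and cid in complexes:
                raise CurationError(f"add of existing complex id: {cid!r}")
            if action in {"replace", "remove"} and cid not in complexes:
                raise CurationError(f"{action} of unknown complex id: {cid!r}")
            if action == "remove":
                del complexes[cid]
            else:
                subunits = _parse_complex_frame(pd.DataFrame([row]).drop(columns="action"))[cid]
                complexes[cid] = subunits
        else:
            iid = str(row["interaction_id"])
            exists = (interactions["interaction_id"] == iid).any()
            if action == "add" and exists:
                raise CurationError(f"add of existing interaction id: {iid!r}")
            if action in {"replace", "remove"} and not exists:
                raise CurationError(f"{action} of unknown interaction id: {iid!r}")
            if action == "remove":
                interactions = interactions[interactions["interaction_id"] != iid]
            else:
                new_row = {c: row.get(c, "") for c in INTERACTION_COLUMNS}
                new_row["interaction_id"] = iid
                if action == "replace":
                    interactions = interactions[interactions["interaction_id"] != iid]
                interactions = pd.concat(
                    [interactions, pd.DataFrame([new_row])], ignore_index=True
                )

    return InteractionDatabase(
        genes=list(db.genes),
        complexes=complexes,
        interactions=interactions.reset_index(drop=True),
        version=db.version,
    )
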