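"""Microenvironments: named sets of co-occurring cell types.

A microenvironment declares which clusters coexist in space and time (for the
endometrium: the lumenal, functional and basal layers, optionally split per
menstrual phase).  Only cluster pairs sharing a microenvironment are eligible
for interaction testing; self-pairs (autocrine signaling) are eligible, and a
pair present in two environments is reported once per environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError

PAIR_COLUMNS = ["cluster_a", "cluster_b", "microenvironment"]


@dataclass(frozen=True)
class Microenvironment:
    name: str
    members: tuple[str, ...]
    phase: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigError(f"microenvironment {self.name!r} has no members")


@dataclass
class MicroenvironmentSet:
    environments: list[Microenvironment]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.environments]
        if len(set(names)) != len(names):
            raise ConfigError("microenvironment names must be unique")

    def __iter__(self):
        return iter(self.environments)

    def __len__(self) -> int:
        return len(self.environments)

    def validate_members(self, clusters_present) -> None:
        """Record a warning for every member label absent from the annotation."""
        present = set(map(str, clusters_present))
        for env in self.environments:
            for m in env.members:
                if m not in present:
                    self.warnings.append(
                        f"microenvironment {env.name!r} member {m!r} matches no cluster"
                    )


def load_microenvironments(table: pd.DataFrame | str) -> MicroenvironmentSet:
    """Build a MicroenvironmentSet from a table with columns cell_type,
    microenvironment and optional phase (TSV path or DataFrame)."""
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t", dtype=str)
    required = {"cell_type", "microenvironment"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigError(f"microenvironment table missing column(s): {sorted(missing)}")
    if table.empty:
        raise ConfigError("microenvironment table is empty")
    envs = []
    for name, grp in table.groupby("microenvironment", sort=False):
        members = tuple(dict.fromkeys(grp["cell_type"].astype(str)))  # dedup, keep order
        phase = None
        if "phase" in grp.columns:
            phases = grp["phase"].dropna().unique()
            phase = str(phases[0]) if len(phases) else None
        envs.append(Microenvironment(name=str(name), members=members, phase=phase))
    return MicroenvironmentSet(envs)


def eligible_pairs(envs: MicroenvironmentSet, clusters_present=None) -> pd.DataFrame:
    """All ordered cluster pairs (self-pairs included) co-occurring in each
    environment, tagged by environment.

    A pair co-occurring in two environments appears twice with distinct tags.
    Members absent from ``clusters_present`` (when given) are dropped with a
    warning, so no emitted pair references a missing cluster.
    """
    if clusters_present is not None:
        envs.validate_members(clusters_present)
        present = set(map(str, clusters_present))
    rows = []
    for env in envs:
        members = [
            m for m in env.members if clusters_present is None or m in present
        ]
        for a in members:
            for b in members:
                rows.append((a, b, env.name))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)
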