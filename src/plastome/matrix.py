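"""Species × gene presence/absence matrix with habitat metadata.

This is the central container for the habitat survey: a boolean matrix
over species and canonical gene symbols, each species carrying one of
three habitat labels (marine, freshwater, brackish).  Presence is
strictly binary — copy number is ignored — and the gene universe is the
union of all inventories, so a gene absent everywhere cannot occur by
construction.  A gene that is simply unannotated in a deposited record
counts as absent; no imputation is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genbank import GeneInventory

__all__ = [
    "HABITATS",
    "parse_habitat",
    "read_habitat_table",
    "PresenceMatrix",
    "build_matrix",
    "unique_gene_sets",
    "write_matrix",
    "read_matrix",
]

HABITATS = ("marine", "freshwater", "brackish")


def parse_habitat(value: str) -> str:
    """Case-insensitive habitat label; anything else is an error."""
    label = value.strip().lower()
    if label not in HABITATS:
        raise ValueError(
            f"unknown habitat {value!r}; expected one of {HABITATS}"
        )
    return label


def read_habitat_table(path: str | Path) -> dict[str, str]:
    """Read a two-column ``species_id<TAB>habitat`` table."""
    habitat: dict[str, str] = {}
    lines = Path(path).read_text().splitlines()
    start = 1 if lines and lines[0].lower().startswith("species") else 0
    for lineno, line in enumerate(lines[start:], start + 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        try:
            habitat[parts[0]] = parse_habitat(parts[1])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return habitat


@dataclass
class PresenceMatrix:
    """Boolean presence matrix (species rows × gene columns) + habitats."""

    presence: pd.DataFrame  # bool, index=species_id, columns=genes
    habitat: dict[str, str]  # species_id -> habitat label

    def __post_init__(self) -> None:
        self.presence = self.presence.astype(bool)
        if self.presence.index.has_duplicates:
            raise ValueError("duplicate species ids")
        if self.presence.columns.has_duplicates:
            raise ValueError("duplicate gene symbols")
        missing = [s for s in self.presence.index if s not in self.habitat]
        if missing:
            raise ValueError(f"species without habitat label: {missing}")
        for species, label in self.habitat.items():
            if label not in HABITATS:
                raise ValueError(f"{species}: unknown habitat {label!r}")

    @property
    def species(self) -> list[str]:
        return list(self.presence.index)

    @property
    def genes(self) -> list[str]:
        return list(self.presence.columns)

    def habitat_counts(self) -> dict[str, int]:
        counts = {h: 0 for h in HABITATS}
        for species in self.presence.index:
            counts[self.habitat[species]] += 1
        return counts


def build_matrix(
    inventories: Iterable[GeneInventory], habitat: Mapping[str, str]
) -> PresenceMatrix:
    """Assemble the presence matrix from inventories and habitat labels.

    The gene universe is the sorted union of all gene sets.  Every
    inventory species must have a habitat label; offenders are listed.
    """
    inventories = list(inventories)
    ids = [inv.species_id for inv in inventories]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate species ids among inventories")
    missing = [i for i in ids if i not in habitat]
    if missing:
        raise ValueError(f"species without habitat label: {missing}")
    universe = sorted(set().union(*(inv.gene_set for inv in inventories)))
    data = {
        inv.species_id: [g in inv.gene_set for g in universe]
        for inv in inventories
    }
    presence = pd.DataFrame.from_dict(
        data, orient="index", columns=universe
    ).loc[ids]
    return PresenceMatrix(
        presence=presence,
        habitat={i: parse_habitat(habitat[i]) for i in ids},
    )


def unique_gene_sets(
    matrix: PresenceMatrix,
    group_a: Sequence[str] | set[str],
    group_b: Sequence[str] | set[str],
) -> tuple[set[str], set[str], set[str]]:
    """Venn-style gene partition for two disjoint species groups.

    Returns ``(only_in_all_of_A, only_in_all_of_B, shared)`` where a
    group-exclusive gene is present in *every* member of that group and
    absent from *every* member of the other, and a shared gene is
    present in every member of both.
    """
    a, b = set(group_a), set(group_b)
    if not a or not b:
        raise ValueError("groups must be non-empty")
    if a & b:
        raise ValueError(f"groups overlap: {sorted(a & b)}")
    unknown = (a | b) - set(matrix.species)
    if unknown:
        raise ValueError(f"species not in matrix: {sorted(unknown)}")
    sub_a = matrix.presence.loc[sorted(a)]
    sub_b = matrix.presence.loc[sorted(b)]
    all_a = sub_a.all(axis=0)
    all_b = sub_b.all(axis=0)
    none_a = ~sub_a.any(axis=0)
    none_b = ~sub_b.any(axis=0)
    only_a = set(matrix.presence.columns[all_a & none_b])
    only_b = set(matrix.presence.columns[all_b & none_a])
    shared = set(matrix.presence.columns[all_a & all_b])
    return only_a, only_b, shared


def write_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    """Write TSV: species_id, habitat, then one 0/1 column per gene."""
    df = matrix.presence.astype(int).copy()
    df.insert(0, "habitat", [matrix.habitat[s] for s in df.index])
    df.index.name = "species_id"
    df.to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> PresenceMatrix:
    df = pd.read_csv(path, sep="\t", index_col="species_id")
    if "habitat" not in df.columns:
        raise ValueError(f"{path}: missing habitat column")
    habitat = {}
    for species, value in df["habitat"].items():
        try:
            habitat[species] = parse_habitat(str(value))
        except ValueError as exc:
            raise ValueError(f"{path}: row {species!r}: {exc}") from exc
    presence = df.drop(columns=["habitat"]).astype(bool)
    return PresenceMatrix(presence=presence, habitat=habitat)
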