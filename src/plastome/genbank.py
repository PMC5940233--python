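"""Reading annotated plastid genome records into gene inventories.

The unit of comparison downstream is the *gene inventory*: the set of
canonical gene symbols annotated on one plastid genome, plus the
genome-summary statistics conventionally reported for organelle
genomes (total length, GC%, feature-kind counts).  Records arrive as
GenBank flat files; parsing is delegated to Biopython and coordinates
are converted once, at the boundary, to 0-based half-open intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .symbols import SynonymTable, normalize_gene_symbol

__all__ = [
    "Feature",
    "AnnotatedGenome",
    "GenomeStats",
    "GeneInventory",
    "read_genbank_record",
    "extract_gene_inventory",
    "genome_summary",
    "write_inventories",
    "read_inventories",
]

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "intron", "other")

# GenBank feature types that mirror other features rather than adding
# annotation of their own.
_SKIP_TYPES = {"source", "gene"}


@dataclass(frozen=True)
class Feature:
    """One annotated feature in internal coordinates.

    ``parts`` are 0-based half-open intervals on the forward strand;
    a joined (e.g. trans-spliced) location keeps all its parts under a
    single feature, because only gene presence matters downstream.
    """

    kind: str
    raw_gene_name: str
    parts: tuple[tuple[int, int], ...]
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for start, end in self.parts:
            if not 0 <= start < end:
                raise ValueError(f"bad interval [{start}, {end})")


@dataclass
class AnnotatedGenome:
    species_id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"{self.species_id}: empty sequence")
        n = len(self.sequence)
        for feat in self.features:
            for start, end in feat.parts:
                if end > n:
                    raise ValueError(
                        f"{self.species_id}: feature interval [{start}, {end}) "
                        f"exceeds sequence length {n}"
                    )


@dataclass(frozen=True)
class GenomeStats:
    """Summary row for one genome: length, GC%, feature counts."""

    total_bp: int
    gc_percent: float
    n_cds: int
    n_trna: int
    n_rrna: int
    n_introns: int


@dataclass
class GeneInventory:
    species_id: str
    gene_set: set[str]
    stats: GenomeStats


def _map_kind(gb_type: str) -> str:
    if gb_type in ("CDS", "tRNA", "rRNA", "intron"):
        return gb_type
    return "other"


def read_genbank_record(
    path: str | Path, species_id: str | None = None
) -> AnnotatedGenome:
    """Parse one GenBank flat file into an :class:`AnnotatedGenome`.

    ``gene`` and ``source`` features are dropped (they duplicate the
    CDS/tRNA/rRNA annotation they envelope).  Feature names come from
    the ``gene`` qualifier with the ``product`` qualifier as fallback;
    a feature with neither is kept with an empty name and a warning.
    GenBank's 1-based inclusive coordinates become 0-based half-open.
    """
    record = SeqIO.read(str(path), "genbank")
    seq = str(record.seq).upper()
    if len(seq) == 0:
        raise ValueError(f"{path}: record has no sequence")
    if species_id is None:
        species_id = record.annotations.get("organism") or record.name

    features: list[Feature] = []
    for gb_feat in record.features:
        if gb_feat.type in _SKIP_TYPES:
            continue
        quals = gb_feat.qualifiers
        name = (quals.get("gene") or quals.get("product") or [""])[0]
        if not name:
            warnings.warn(
                f"{species_id}: {gb_feat.type} feature at {gb_feat.location} "
                "has no gene/product qualifier"
            )
        # Biopython locations are already 0-based half-open.
        parts = tuple(
            (int(p.start), int(p.end)) for p in gb_feat.location.parts
        )
        strand = "-" if gb_feat.location.strand == -1 else "+"
        features.append(
            Feature(
                kind=_map_kind(gb_feat.type),
                raw_gene_name=name,
                parts=parts,
                strand=strand,
            )
        )
    return AnnotatedGenome(species_id=species_id, sequence=seq, features=features)


def genome_summary(genome: AnnotatedGenome) -> GenomeStats:
    """Genome statistics: GC% over unambiguous bases, feature tallies.

    GC% is 100·(G+C)/(A+C+G+T), ignoring ambiguity codes, rounded to
    one decimal as conventionally printed for organelle genomes.
    """
    seq = genome.sequence
    if len(seq) == 0:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    if acgt == 0:
        raise ValueError(f"{genome.species_id}: no unambiguous bases")
    counts = {kind: 0 for kind in FEATURE_KINDS}
    for feat in genome.features:
        counts[feat.kind] += 1
    return GenomeStats(
        total_bp=len(seq),
        gc_percent=round(100.0 * gc / acgt, 1),
        n_cds=counts["CDS"],
        n_trna=counts["tRNA"],
        n_rrna=counts["rRNA"],
        n_introns=counts["intron"],
    )


def extract_gene_inventory(
    genome: AnnotatedGenome, table: SynonymTable | None = None
) -> GeneInventory:
    """Normalized CDS gene set plus summary stats for one genome.

    Duplicate gene copies collapse to one set member; unnamed CDS
    features are excluded from the set (they were warned about at
    parse time).
    """
    gene_set = {
        normalize_gene_symbol(feat.raw_gene_name, table)
        for feat in genome.features
        if feat.kind == "CDS" and feat.raw_gene_name.strip()
    }
    return GeneInventory(
        species_id=genome.species_id,
        gene_set=gene_set,
        stats=genome_summary(genome),
    )


_INV_COLUMNS = [
    "species_id",
    "total_bp",
    "gc_percent",
    "n_cds",
    "n_trna",
    "n_rrna",
    "n_introns",
    "genes",
]


def write_inventories(
    inventories: Iterable[GeneInventory], path: str | Path
) -> None:
    """Write inventories as TSV (one row per species, genes comma-joined)."""
    lines = ["\t".join(_INV_COLUMNS)]
    for inv in inventories:
        s = inv.stats
        lines.append(
            "\t".join(
                [
                    inv.species_id,
                    str(s.total_bp),
                    f"{s.gc_percent:.1f}",
                    str(s.n_cds),
                    str(s.n_trna),
                    str(s.n_rrna),
                    str(s.n_introns),
                    ",".join(sorted(inv.gene_set)),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_inventories(path: str | Path) -> list[GeneInventory]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != _INV_COLUMNS:
        raise ValueError(f"{path}: not an inventory table")
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        (sid, bp, gc, cds, trna, rrna, introns, genes) = line.split("\t")
        out.append(
            GeneInventory(
                species_id=sid,
                gene_set=set(genes.split(",")) if genes else set(),
                stats=GenomeStats(
                    total_bp=int(bp),
                    gc_percent=float(gc),
                    n_cds=int(cds),
                    n_trna=int(trna),
                    n_rrna=int(rrna),
                    n_introns=int(introns),
                ),
            )
        )
    return out


def summary_table(inventories: Sequence[GeneInventory]):
    """Genome-feature comparison table (one row per species) as a DataFrame."""
    import pandas as pd

    rows = [
        {
            "species_id": inv.species_id,
            "total_bp": inv.stats.total_bp,
            "gc_percent": inv.stats.gc_percent,
            "n_introns": inv.stats.n_introns,
            "n_cds": inv.stats.n_cds,
            "n_trna": inv.stats.n_trna,
            "n_rrna": inv.stats.n_rrna,
        }
        for inv in inventories
    ]
    return pd.DataFrame(rows).set_index("species_id")
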