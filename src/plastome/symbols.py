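"""Canonicalization of plastid gene names.

Gene names in deposited organelle records are inconsistent across
depositors: case varies (``PbsA`` / ``pbsA``), ``ycf`` numbers are
sometimes zero-padded (``ycf034``), duplicated copies carry locus
suffixes (``psbA_2``), and some records only name a feature through its
``product`` qualifier ("heme oxygenase").  Cross-species gene-content
comparison needs a single canonical symbol per gene, so every raw name
passes through :func:`normalize_gene_symbol`, optionally backed by a
:class:`SynonymTable` of known aliases.

The canonical form follows the standard plastid convention: a three
letter lower-case stem, the remaining letters kept verbatim
(``rbcL``, ``psbA``), numeric suffixes without leading zeros
(``ycf34``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = ["SynonymTable", "normalize_gene_symbol", "load_default_synonyms"]

# separator + trailing copy/locus token, e.g. "psbA_2", "rbcL.1", "ycf34-b"
_LOCUS_SUFFIX = re.compile(r"[_.\-](copy)?[0-9]+$|[_.\-][a-z]$")
_SYMBOL = re.compile(r"^([A-Za-z]{2,})([0-9]*)$")


def _fold_key(raw: str) -> str:
    """Lookup key: lower case, internal whitespace collapsed."""
    return " ".join(raw.lower().split())


def _canonical_case(name: str) -> str:
    m = _SYMBOL.match(name)
    if m is None:
        return _fold_key(name)
    letters, digits = m.groups()
    stem = letters[:3].lower() + letters[3:]
    if digits:
        digits = str(int(digits))  # zero-pad removal
    return stem + digits


@dataclass
class SynonymTable:
    """Functional mapping from raw gene names to canonical symbols.

    Keys are matched case-insensitively with collapsed whitespace, so a
    ``product`` qualifier such as "Heme  oxygenase" resolves like
    "heme oxygenase".  Canonical values must be fixed points of
    :func:`normalize_gene_symbol` (checked on construction).
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        folded = {}
        for raw, canon in self.mapping.items():
            if normalize_gene_symbol(canon) != canon:
                raise ValueError(
                    f"synonym target {canon!r} is not a canonical symbol"
                )
            folded[_fold_key(raw)] = canon
        self.mapping = folded

    def get(self, raw: str) -> str | None:
        return self.mapping.get(_fold_key(raw))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SynonymTable":
        """Read a two-column ``raw<TAB>canonical`` table ('#' comments)."""
        mapping: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            mapping[parts[0]] = parts[1]
        return cls(mapping)


def normalize_gene_symbol(raw: str, table: SynonymTable | None = None) -> str:
    """Map a raw gene or product name to its canonical symbol.

    Idempotent: ``normalize(normalize(x)) == normalize(x)``.  Known
    synonyms (including free-text product names) are resolved through
    *table*; unknown names are case-folded to the plastid convention
    with trailing locus suffixes stripped.
    """
    name = raw.strip()
    if not name:
        raise ValueError("empty gene name")
    if table is not None:
        hit = table.get(name)
        if hit is not None:
            return hit
    name = _LOCUS_SUFFIX.sub("", name)
    canon = _canonical_case(name)
    if table is not None:
        hit = table.get(canon)
        if hit is not None:
            return hit
    return canon


def load_default_synonyms() -> SynonymTable:
    """The synonym table shipped with the package.

    Covers the product-qualifier spellings commonly used for the
    habitat-screen genes (heme oxygenase, glutaredoxin, the ycf ORFs)
    plus a few frequently aliased photosynthesis genes.
    """
    with resources.as_file(
        resources.files("plastome.data").joinpath("synonyms.tsv")
    ) as p:
        return SynonymTable.from_tsv(p)
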