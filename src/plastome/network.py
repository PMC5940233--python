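"""EGN-style protein similarity network from pairwise hit tables.

Nodes are all sequences in the lengths table (so proteins with no
surviving hit stay visible as singletons); an edge joins two proteins
when at least one pairwise hit passes every published connection
threshold:

* e-value ≤ 1e-05,
* percent identity ≥ 20,
* alignment covering ≥ 20% of the shorter sequence, and
* alignment covering ≥ 70% of *both* sequences.

The two coverage clauses are applied conjunctively as stated (the 20%
clause is then redundant but kept for fidelity to the published EGN
settings).  Coverage is computed from the alignment-length column of
the 12-column BLAST tabular format, per HSP, without subtracting gaps.
Connected components of the resulting graph approximate gene families.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Hit",
    "HitParseError",
    "Thresholds",
    "read_hits_tabular",
    "filter_hits",
    "build_network",
    "connected_components",
    "write_edge_list",
]


@dataclass(frozen=True)
class Hit:
    """One row of a BLAST outfmt-6 style tabular file."""

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    e_value: float
    bit_score: float
    extra: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("e-value must be > 0")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity outside [0, 100]")


@dataclass(frozen=True)
class HitParseError:
    lineno: int
    line: str
    reason: str


@dataclass(frozen=True)
class Thresholds:
    """EGN connection thresholds (defaults = published settings)."""

    max_evalue: float = 1e-5
    min_identity: float = 20.0
    min_shortest_coverage: float = 0.20
    min_mutual_coverage: float = 0.70


def read_hits_tabular(
    path: str | Path,
) -> tuple[list[Hit], list[HitParseError]]:
    """Parse a ≥12-column whitespace/tab-delimited hit table.

    Malformed lines are not fatal: they are collected into the second
    element of the returned tuple.  An empty file yields no hits.
    """
    hits: list[Hit] = []
    errors: list[HitParseError] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 12:
            errors.append(HitParseError(lineno, line, "fewer than 12 columns"))
            continue
        try:
            hit = Hit(
                query_id=cols[0],
                subject_id=cols[1],
                percent_identity=float(cols[2]),
                align_length=int(cols[3]),
                e_value=float(cols[10]),
                bit_score=float(cols[11]),
                extra=tuple(cols[4:10]),
            )
        except ValueError as exc:
            errors.append(HitParseError(lineno, line, str(exc)))
            continue
        hits.append(hit)
    return hits, errors


def _passes(hit: Hit, lengths: Mapping[str, int], t: Thresholds) -> bool:
    lq, ls = lengths[hit.query_id], lengths[hit.subject_id]
    return (
        hit.e_value <= t.max_evalue
        and hit.percent_identity >= t.min_identity
        and hit.align_length >= t.min_shortest_coverage * min(lq, ls)
        and hit.align_length >= t.min_mutual_coverage * lq
        and hit.align_length >= t.min_mutual_coverage * ls
    )


def filter_hits(
    hits: Iterable[Hit],
    lengths: Mapping[str, int],
    thresholds: Thresholds = Thresholds(),
) -> list[tuple[str, str, Hit]]:
    """Edge list of hits passing all thresholds.

    Self-hits are removed and reciprocal duplicates collapsed, keeping
    the hit with the lowest e-value per unordered pair.  A hit naming a
    sequence without a known length is an error.
    """
    hits = list(hits)
    unknown = sorted(
        {h.query_id for h in hits if h.query_id not in lengths}
        | {h.subject_id for h in hits if h.subject_id not in lengths}
    )
    if unknown:
        raise KeyError(f"hits reference sequences of unknown length: {unknown}")
    best: dict[tuple[str, str], Hit] = {}
    for hit in hits:
        if hit.query_id == hit.subject_id:
            continue
        if not _passes(hit, lengths, thresholds):
            continue
        key = tuple(sorted((hit.query_id, hit.subject_id)))
        if key not in best or hit.e_value < best[key].e_value:
            best[key] = hit
    return [(q, s, hit) for (q, s), hit in sorted(best.items())]


def build_network(
    hits: Iterable[Hit],
    lengths: Mapping[str, int],
    thresholds: Thresholds = Thresholds(),
) -> nx.Graph:
    """Similarity graph over the full sequence universe."""
    graph = nx.Graph()
    for seq_id, length in lengths.items():
        graph.add_node(seq_id, length=int(length))
    for q, s, hit in filter_hits(hits, lengths, thresholds):
        graph.add_edge(
            q,
            s,
            e_value=hit.e_value,
            percent_identity=hit.percent_identity,
            align_length=hit.align_length,
        )
    return graph


def connected_components(graph: nx.Graph) -> list[set[str]]:
    """Components (singletons included), largest first, ties by name."""
    comps = [set(c) for c in nx.connected_components(graph)]
    comps.sort(key=lambda c: (-len(c), sorted(c)))
    return comps


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    lines = ["query_id\tsubject_id\te_value\tpercent_identity\talign_length"]
    for q, s, data in sorted(graph.edges(data=True)):
        lines.append(
            f"{q}\t{s}\t{data['e_value']:.3e}"
            f"\t{data['percent_identity']:.2f}\t{data['align_length']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
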