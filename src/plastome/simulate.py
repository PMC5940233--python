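"""Synthetic data with the statistical structure the analysis assumes.

Every pipeline stage can be exercised without downloads: trees (star or
Yule), two-state habitat evolution along branches, habitat-dependent
per-gene Bernoulli loss (tip-wise, or irreversible branch-wise loss for
phylogenetically clustered scenarios), syntactically valid toy GenBank
records, proteins with planted TM segments / transit peptides / domain
copies, and toy BLAST-tabular hit tables.  All generators are
deterministic under the configured seed.

The default configuration mirrors the composition of the published
red-algal plastid survey: 109 marine, 16 freshwater and 2 brackish
species, with habitat-specific loss probabilities for the focal gene
set (e.g. pbsA absent from 16/116 marine-like but 12/16 freshwater
genomes, i.e. loss probabilities of roughly 0.14 and 0.75).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Literal

import dendropy
import numpy as np
import pandas as pd

from .genbank import GeneInventory, GenomeStats
from .matrix import PresenceMatrix
from .proteins import AMINO_ACIDS, ProteinRecord, load_default_domain_profile

__all__ = [
    "GeneLossSpec",
    "SimulationConfig",
    "simulate_tree",
    "simulate_habitat",
    "simulate_gene_loss",
    "emit_toy_genbank",
    "plant_tm_protein",
    "simulate_hit_table",
]


@dataclass(frozen=True)
class GeneLossSpec:
    symbol: str
    loss_prob_marine: float
    loss_prob_freshwater: float

    def __post_init__(self) -> None:
        for p in (self.loss_prob_marine, self.loss_prob_freshwater):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.symbol}: loss prob {p} outside [0,1]")

    @property
    def habitat_effect(self) -> bool:
        return self.loss_prob_marine != self.loss_prob_freshwater


def default_genes() -> list[GeneLossSpec]:
    """Focal habitat-screen genes with survey-like loss probabilities."""
    return [
        GeneLossSpec("pbsA", 0.14, 0.75),
        GeneLossSpec("ycf34", 0.12, 0.80),
        GeneLossSpec("ycf35", 0.20, 0.70),
        GeneLossSpec("ycf46", 0.10, 0.85),
        GeneLossSpec("ycf37", 0.30, 0.60),
        GeneLossSpec("grx", 0.30, 0.60),
        GeneLossSpec("ycf91", 0.90, 0.20),
    ]


@dataclass
class SimulationConfig:
    n_marine: int = 109
    n_freshwater: int = 16
    n_brackish: int = 2
    tree_model: Literal["star", "yule"] = "star"
    birth_rate: float = 1.0
    habitat_transition_rate: float = 0.1
    genes: list[GeneLossSpec] = field(default_factory=default_genes)
    loss_mode: Literal["tip", "branch"] = "tip"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_marine, self.n_freshwater, self.n_brackish) < 0:
            raise ValueError("tip counts must be non-negative")
        if self.habitat_transition_rate < 0:
            raise ValueError("habitat transition rate must be >= 0")

    @property
    def n_tips(self) -> int:
        return self.n_marine + self.n_freshwater + self.n_brackish


def _tip_labels(n: int) -> list[str]:
    return [f"sp{i + 1:04d}" for i in range(n)]


def simulate_tree(config: SimulationConfig) -> dendropy.Tree:
    """Star tree (independent tips) or seeded Yule tree with lengths."""
    n = config.n_tips
    if n < 2:
        raise ValueError("need at least 2 tips")
    labels = _tip_labels(n)
    if config.tree_model == "star":
        taxa = dendropy.TaxonNamespace(labels)
        tree = dendropy.Tree(taxon_namespace=taxa)
        for label in labels:
            child = tree.seed_node.new_child(edge_length=1.0)
            child.taxon = taxa.get_taxon(label)
        tree.is_rooted = True
        return tree
    if config.tree_model == "yule":
        from dendropy.simulate import treesim

        rng = random.Random(config.seed)
        taxa = dendropy.TaxonNamespace(labels)
        tree = treesim.birth_death_tree(
            birth_rate=config.birth_rate,
            death_rate=0.0,
            num_extant_tips=n,
            taxon_namespace=taxa,
            rng=rng,
        )
        tree.is_rooted = True
        return tree
    raise ValueError(f"unknown tree model {config.tree_model!r}")


def simulate_habitat(
    tree: dendropy.Tree, config: SimulationConfig
) -> dict[str, str]:
    """Assign habitats to tips.

    On a star tree the configured marine/freshwater counts are assigned
    directly (shuffled).  Otherwise a symmetric two-state Markov chain
    (marine ↔ freshwater, rate per unit branch length) runs root-to-tip
    from a marine root; the closed-form switch probability over a
    branch of length t is (1 − exp(−2qt))/2.  The configured number of
    brackish tips is then drawn at random among tips.  Node habitats
    are stored on the tree (``node.habitat``) for branch-wise loss.
    """
    rng = random.Random(config.seed * 65537 + 1)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if config.tree_model == "star":
        if len(tips) != config.n_tips:
            raise ValueError("tree tip count does not match configuration")
        pool = (
            ["marine"] * config.n_marine
            + ["freshwater"] * config.n_freshwater
            + ["brackish"] * config.n_brackish
        )
        rng.shuffle(pool)
        habitats = dict(zip(tips, pool))
        for node in tree.preorder_node_iter():
            node.habitat = "marine"
        for leaf in tree.leaf_node_iter():
            leaf.habitat = habitats[leaf.taxon.label]
        return {t: habitats[t] for t in tips}
    else:
        q = config.habitat_transition_rate
        other = {"marine": "freshwater", "freshwater": "marine"}
        habitats = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                node.habitat = "marine"
                continue
            t = node.edge.length or 0.0
            p_switch = 0.5 * (1.0 - np.exp(-2.0 * q * t))
            state = node.parent_node.habitat
            if rng.random() < p_switch:
                state = other[state]
            node.habitat = state
            if node.is_leaf():
                habitats[node.taxon.label] = state
    brackish = rng.sample(tips, config.n_brackish) if config.n_brackish else []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label in brackish:
            leaf.habitat = "brackish"
            habitats[leaf.taxon.label] = "brackish"
    return {t: habitats[t] for t in tips}


def simulate_gene_loss(
    tree: dendropy.Tree,
    habitats: dict[str, str],
    config: SimulationConfig,
) -> tuple[PresenceMatrix, pd.DataFrame]:
    """Habitat-dependent gene loss; returns the matrix and a truth table.

    Every gene is present at the root.  In ``tip`` mode each tip loses
    the gene independently with the loss probability of its habitat
    (brackish tips use the marine probability) — the independence
    regime the chi-square screen assumes.  In ``branch`` mode the loss
    probabilities are read as per-unit-length loss rates and a gene,
    once lost on a branch (prob 1 − exp(−rate·length), rate by the
    child node's habitat), stays absent in the whole subtree — the
    phylogenetically clustered regime.

    Genes lost everywhere are dropped from the matrix universe with a
    warning; the truth table flags which genes carry a habitat effect.
    """
    import warnings

    if not config.genes:
        raise ValueError("no gene parameters configured")
    rng = random.Random(config.seed * 65537 + 2)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    presence: dict[str, list[bool]] = {}
    for gene in config.genes:
        prob = {
            "marine": gene.loss_prob_marine,
            "brackish": gene.loss_prob_marine,
            "freshwater": gene.loss_prob_freshwater,
        }
        if config.loss_mode == "tip":
            states = [rng.random() >= prob[habitats[t]] for t in tips]
        else:
            lost: dict = {}
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    lost[node] = False
                    continue
                if lost[node.parent_node]:
                    lost[node] = True
                    continue
                t = node.edge.length or 0.0
                rate = prob[getattr(node, "habitat", "marine")]
                lost[node] = rng.random() < 1.0 - np.exp(-rate * t)
            by_tip = {
                leaf.taxon.label: not lost[leaf]
                for leaf in tree.leaf_node_iter()
            }
            states = [by_tip[t] for t in tips]
        if not any(states):
            warnings.warn(
                f"{gene.symbol}: lost in every tip; dropped from matrix"
            )
            continue
        presence[gene.symbol] = states

    frame = pd.DataFrame(presence, index=tips)
    truth = pd.DataFrame(
        [
            {
                "gene": g.symbol,
                "loss_prob_marine": g.loss_prob_marine,
                "loss_prob_freshwater": g.loss_prob_freshwater,
                "habitat_effect": g.habitat_effect,
                "in_matrix": g.symbol in presence,
            }
            for g in config.genes
        ]
    )
    matrix = PresenceMatrix(presence=frame, habitat=dict(habitats))
    return matrix, truth


_BASES = "ACGT"


def emit_toy_genbank(
    inventory: GeneInventory | set[str],
    seed: int = 0,
    species_id: str = "toy species",
    gc: float = 0.30,
    gene_length: int = 300,
    spacer_length: int = 60,
) -> str:
    """Render a small, valid GenBank record with one CDS per gene.

    Genes are laid head-to-tail with random intergenic spacers whose
    base composition follows the configured GC fraction.  Reading the
    record back recovers the gene set exactly (round-trip identity).
    """
    from io import StringIO

    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    if isinstance(inventory, GeneInventory):
        genes = sorted(inventory.gene_set)
        species_id = inventory.species_id
    else:
        genes = sorted(inventory)
    if not genes:
        raise ValueError("empty inventory")

    rng = random.Random(seed)

    def draw(n: int) -> str:
        out = []
        for _ in range(n):
            if rng.random() < gc:
                out.append(rng.choice("GC"))
            else:
                out.append(rng.choice("AT"))
        return "".join(out)

    seq_parts: list[str] = []
    features = []
    pos = 0
    for gene in genes:
        spacer = draw(spacer_length)
        seq_parts.append(spacer)
        pos += len(spacer)
        body = draw(gene_length)
        features.append(
            SeqFeature(
                FeatureLocation(pos, pos + len(body), strand=1),
                type="CDS",
                qualifiers={"gene": [gene]},
            )
        )
        seq_parts.append(body)
        pos += len(body)
    seq_parts.append(draw(spacer_length))

    record = SeqRecord(
        Seq("".join(seq_parts)),
        id="TOY000001",
        name="TOY000001",
        description=f"synthetic toy plastid genome of {species_id}",
        annotations={"molecule_type": "DNA", "organism": species_id},
        features=features,
    )
    buf = StringIO()
    SeqIO.write(record, buf, "genbank")
    return buf.getvalue()


_HYDROPHILIC = "DEKRSTNQGP"


def plant_tm_protein(
    n_tm: int,
    transit: bool,
    seed: int = 0,
    seq_id: str = "planted",
    encoded_in: Literal["plastid", "nucleus", "unknown"] = "unknown",
    include_domain: bool = True,
    tm_length: int = 25,
    backbone_length: int = 140,
) -> tuple[ProteinRecord, dict]:
    """Protein with a planted architecture plus its ground truth.

    The backbone is hydrophilic; ``n_tm`` poly-Leu stretches are
    inserted, the last one C-terminal; an optional Ser-rich 40-residue
    transit prefix and a copy of the packaged toy heme-oxygenase domain
    consensus can be planted.  The returned truth dict records the
    planted coordinates and drives classifier tests.
    """
    if n_tm < 0:
        raise ValueError("n_tm must be >= 0")
    rng = random.Random(seed)

    def hydrophilic(n: int) -> str:
        return "".join(rng.choice(_HYDROPHILIC) for _ in range(n))

    pieces: list[str] = []
    truth: dict = {"n_tm": n_tm, "transit": transit, "tm_positions": []}
    if transit:
        prefix = "MA" + "".join(
            rng.choice("SSSTA") for _ in range(38)
        )
        pieces.append(prefix)
    else:
        # transit-negative by construction: no Ser/Thr in the head
        pieces.append("M" + "".join(rng.choice("DEKRNQG") for _ in range(9)))

    if include_domain:
        profile = load_default_domain_profile()
        # most-likely residue per profile column = plantable consensus
        consensus = "".join(
            AMINO_ACIDS[i] for i in profile.matrix.argmax(axis=1)
        )
        start = sum(len(p) for p in pieces)
        pieces.append(consensus)
        truth["domain_span"] = (start, start + len(consensus))
    else:
        truth["domain_span"] = None
        pieces.append(hydrophilic(60))

    pieces.append(hydrophilic(backbone_length))
    internal_tms = max(0, n_tm - 1)
    for _ in range(internal_tms):
        start = sum(len(p) for p in pieces)
        pieces.append("L" * tm_length)
        truth["tm_positions"].append((start, start + tm_length))
        pieces.append(hydrophilic(40))
    if n_tm >= 1:
        start = sum(len(p) for p in pieces)
        pieces.append("L" * tm_length)
        truth["tm_positions"].append((start, start + tm_length))
        pieces.append(hydrophilic(8))

    record = ProteinRecord(
        seq_id=seq_id, sequence="".join(pieces), encoded_in=encoded_in
    )
    return record, truth


def simulate_hit_table(
    n_clusters: int = 3,
    cluster_size: int = 4,
    seed: int = 0,
    seq_length: int = 200,
) -> tuple[str, dict[str, int], list[set[str]]]:
    """Toy BLAST-tabular hit table with planted cluster structure.

    Within-cluster hits pass the published network thresholds; a few
    between-cluster hits are planted *below* threshold (weak e-value or
    low coverage) so threshold filtering must separate the clusters.
    Returns (tabular text, sequence lengths, expected components).
    """
    rng = random.Random(seed)
    lengths: dict[str, int] = {}
    clusters: list[set[str]] = []
    lines: list[str] = []

    def row(q, s, ident, alen, evalue):
        mism = int(alen * (100 - ident) / 100)
        return (
            f"{q}\t{s}\t{ident:.2f}\t{alen}\t{mism}\t0\t1\t{alen}\t1\t{alen}"
            f"\t{evalue:.2e}\t{alen * 2:.1f}"
        )

    for c in range(n_clusters):
        members = [f"c{c}_s{i}" for i in range(cluster_size)]
        clusters.append(set(members))
        for m in members:
            lengths[m] = seq_length + rng.randint(-10, 10)
        for i, q in enumerate(members):
            for s in members[i + 1 :]:
                alen = int(0.9 * min(lengths[q], lengths[s]))
                lines.append(
                    row(q, s, rng.uniform(40, 90), alen, 10 ** rng.uniform(-50, -10))
                )
    # planted sub-threshold between-cluster noise
    for c in range(n_clusters - 1):
        q = f"c{c}_s0"
        s = f"c{c + 1}_s0"
        lines.append(row(q, s, 35.0, int(0.8 * seq_length), 1e-3))  # e-value fails
        lines.append(row(q, s, 25.0, 30, 1e-20))  # coverage fails
    return "\n".join(lines) + "\n", lengths, clusters
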