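"""Parsimony mapping of gene presence/absence on a rooted phylogeny.

Gene losses in plastid genomes tend to be phylogenetically clustered
rather than scattered, so the screen's per-gene presence patterns are
mapped onto a (user-supplied, rooted) tree and summarized by the
minimum number of state changes under Fitch small parsimony.  The
generalized (Hartigan) rule handles multifurcations; branch lengths
are ignored — the mapping is qualitative.

Because plastid genes are ancestrally present, changes are polarized
on a top-down pass from a present root (configurable), splitting
``min_changes`` into losses (present→absent) and gains.  Ties at
internal nodes are resolved toward the parent's state, which delays
changes toward the tips; this is one optimal labeling among possibly
many — the change count itself is labeling-independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping, Sequence

import dendropy
import pandas as pd

from .matrix import HABITATS, PresenceMatrix

__all__ = [
    "read_newick",
    "parse_newick",
    "fitch_parsimony",
    "count_losses_gains",
    "CharacterMap",
    "character_map",
    "clade_presence_summary",
]

PRESENT = "present"
ABSENT = "absent"


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a rooted Newick string; duplicate tip labels are an error."""
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    tree.is_rooted = True
    return tree


def read_newick(path: str | Path) -> dendropy.Tree:
    return parse_newick(Path(path).read_text())


def _tip_label(node: dendropy.Node) -> str:
    return node.taxon.label


def _hartigan_down(
    tree: dendropy.Tree, tip_states: Mapping[str, str]
) -> tuple[int, dict]:
    """Bottom-up pass: optimal state sets and the minimum change count.

    At each internal node, each state is scored by how many children
    admit it; the optimal set keeps the top scorers and the node adds
    (n_children − top score) changes.  On binary trees this reduces to
    the classic Fitch intersection/union rule.
    """
    min_changes = 0
    optimal: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = _tip_label(node)
            if label not in tip_states:
                raise KeyError(f"tip {label!r} has no state")
            state = tip_states[label]
            if state not in (PRESENT, ABSENT):
                raise ValueError(f"{label}: bad state {state!r}")
            optimal[node] = {state}
        else:
            count = {PRESENT: 0, ABSENT: 0}
            children = node.child_nodes()
            for child in children:
                for state in optimal[child]:
                    count[state] += 1
            best = max(count.values())
            optimal[node] = {s for s, c in count.items() if c == best}
            min_changes += len(children) - best
    return min_changes, optimal


def _resolve_root(
    root_set: set, root_state_assumption: Literal["present", "infer"]
) -> str:
    if root_state_assumption == "present":
        return PRESENT if PRESENT in root_set else ABSENT
    # infer: take the optimal state, ties toward presence (plastid genes
    # are ancestrally present)
    return PRESENT if PRESENT in root_set else next(iter(root_set))


def _label_top_down(
    tree: dendropy.Tree,
    optimal: dict,
    root_state: str,
) -> dict[dendropy.Node, str]:
    states: dict[dendropy.Node, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = root_state
            continue
        parent_state = states[node.parent_node]
        if parent_state in optimal[node]:
            states[node] = parent_state  # tie-break toward the parent
        else:
            states[node] = next(iter(optimal[node]))
    return states


def fitch_parsimony(
    tree: dendropy.Tree,
    tip_states: Mapping[str, str],
    root_state_assumption: Literal["present", "infer"] = "infer",
) -> tuple[int, dict[dendropy.Node, str]]:
    """Minimum change count and one optimal node labeling.

    Every tip label in the tree must have a state in *tip_states*
    (``"present"`` / ``"absent"``).  Returns ``(min_changes, states)``
    where ``states`` maps every node (tips included) to its state in
    one most-parsimonious labeling.
    """
    min_changes, optimal = _hartigan_down(tree, tip_states)
    root_state = _resolve_root(
        optimal[tree.seed_node], root_state_assumption
    )
    states = _label_top_down(tree, optimal, root_state)
    return min_changes, states


def count_losses_gains(
    tree: dendropy.Tree,
    tip_states: Mapping[str, str],
    root_state_assumption: Literal["present", "infer"] = "present",
) -> tuple[int, int]:
    """Split the parsimony changes into losses and gains.

    A change on a branch is a loss when the parent is present and the
    child absent, a gain in the opposite direction.  The root is set to
    the assumed ancestral state when that state is optimal (it breaks
    ties and otherwise yields the inferred optimum, so the loss+gain
    total always equals ``min_changes``).
    """
    min_changes, states = fitch_parsimony(
        tree, tip_states, root_state_assumption
    )
    losses = gains = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent, child = states[node.parent_node], states[node]
        if parent == PRESENT and child == ABSENT:
            losses += 1
        elif parent == ABSENT and child == PRESENT:
            gains += 1
    assert losses + gains == min_changes
    return losses, gains


@dataclass
class CharacterMap:
    """One gene's presence/absence mapped on the tree."""

    gene: str
    tip_states: dict[str, str]
    internal_states: dict[str, str]  # node id -> state
    min_changes: int
    n_losses: int
    n_gains: int


def _node_id(node: dendropy.Node, index: int) -> str:
    if node.is_leaf():
        return _tip_label(node)
    if node.label:
        return node.label
    return f"node{index}"


def character_map(
    tree: dendropy.Tree,
    matrix: PresenceMatrix,
    gene: str,
    root_state_assumption: Literal["present", "infer"] = "present",
) -> CharacterMap:
    """Map one matrix gene on the tree (species must all be tips)."""
    tips = {_tip_label(l) for l in tree.leaf_node_iter()}
    missing = [s for s in matrix.species if s not in tips]
    if missing:
        raise ValueError(f"matrix species missing from tree: {missing}")
    tip_states = {
        s: PRESENT if matrix.presence.at[s, gene] else ABSENT
        for s in matrix.species
    }
    min_changes, states = fitch_parsimony(
        tree, tip_states, root_state_assumption
    )
    losses, gains = count_losses_gains(
        tree, tip_states, root_state_assumption
    )
    internal = {}
    for i, node in enumerate(tree.preorder_node_iter()):
        if not node.is_leaf():
            internal[_node_id(node, i)] = states[node]
    return CharacterMap(
        gene=gene,
        tip_states=tip_states,
        internal_states=internal,
        min_changes=min_changes,
        n_losses=losses,
        n_gains=gains,
    )


def clade_presence_summary(
    tree: dendropy.Tree,
    matrix: PresenceMatrix,
    genes: Sequence[str],
) -> pd.DataFrame:
    """Per-internal-node gene presence fractions and habitat makeup.

    One row per internal node: the number of descendant tips that are
    in the matrix, the fraction of them carrying each gene, and the
    habitat composition of the clade.  Useful for spotting clade-wide
    losses (all-absent clades) and their habitat context.
    """
    tips = {_tip_label(l) for l in tree.leaf_node_iter()}
    missing = [s for s in matrix.species if s not in tips]
    if missing:
        raise ValueError(f"matrix species missing from tree: {missing}")
    for gene in genes:
        if gene not in matrix.presence.columns:
            raise KeyError(f"gene {gene!r} not in matrix")
    in_matrix = set(matrix.species)
    rows = []
    for i, node in enumerate(tree.preorder_node_iter()):
        if node.is_leaf():
            continue
        clade = [
            _tip_label(l)
            for l in node.leaf_iter()
            if _tip_label(l) in in_matrix
        ]
        if not clade:
            continue
        row: dict = {"node": _node_id(node, i), "n_tips": len(clade)}
        sub = matrix.presence.loc[clade]
        for gene in genes:
            row[f"{gene}_presence"] = float(sub[gene].mean())
        for habitat in HABITATS:
            row[f"n_{habitat}"] = sum(
                1 for s in clade if matrix.habitat[s] == habitat
            )
        rows.append(row)
    return pd.DataFrame(rows)


def annotated_newick(
    tree: dendropy.Tree, states: Mapping[dendropy.Node, str]
) -> str:
    """Newick string with internal-state comments on each node."""
    clone = tree.clone(depth=1)  # preserves preorder structure
    for node, orig in zip(
        clone.preorder_node_iter(), tree.preorder_node_iter()
    ):
        node.annotations.add_new("state", states[orig])
    return clone.as_string(schema="newick", suppress_annotations=False)
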