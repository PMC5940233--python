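"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-derivations (exhaustive
enumeration, closed-form combinatorics) kept independent of the
library code paths they check.
"""

from __future__ import annotations

import itertools
import random
from math import comb

import pytest

from plastome.genbank import GeneInventory, GenomeStats
from plastome.matrix import build_matrix
from plastome.symbols import load_default_synonyms

# ---------------------------------------------------------------- oracles


def brute_force_parsimony(tree, tip_states):
    """Minimum changes by exhaustive enumeration of internal labelings."""
    internal = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    best = None
    for labels in itertools.product(("present", "absent"), repeat=len(internal)):
        state = dict(zip(internal, labels))
        for leaf in tree.leaf_node_iter():
            state[leaf] = tip_states[leaf.taxon.label]
        changes = sum(
            1
            for node in tree.preorder_node_iter()
            if node.parent_node is not None
            and state[node] != state[node.parent_node]
        )
        if best is None or changes < best:
            best = changes
    return best


def random_rooted_tree(rng: random.Random, n_tips: int, multifurcate=True):
    """Random rooted tree shape as a Newick string over tips t1..tn."""
    nodes = [f"t{i + 1}" for i in range(n_tips)]
    rng.shuffle(nodes)
    while len(nodes) > 1:
        max_k = min(len(nodes), 4 if multifurcate else 2)
        k = rng.randint(2, max_k) if max_k > 2 else 2
        children = [nodes.pop() for _ in range(k)]
        nodes.append("(" + ",".join(children) + ")")
        rng.shuffle(nodes)
    return nodes[0] + ";"


def pearson_chi2(a, b, c, d):
    """Hand formula for the 2×2 Pearson statistic."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def permutation_pvalue(a, b, c, d):
    """Exact conditional permutation p-value of the chi-square statistic.

    Fixes both margins and enumerates the hypergeometric distribution
    of the top-left cell; p = probability of a table at least as
    extreme (chi2 >= observed).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    observed = pearson_chi2(a, b, c, d)
    p = 0.0
    denom = comb(n, c1)
    for a2 in range(max(0, c1 - r2), min(r1, c1) + 1):
        stat = pearson_chi2(a2, r1 - a2, c1 - a2, r2 - (c1 - a2))
        if stat >= observed - 1e-12:
            p += comb(r1, a2) * comb(r2, c1 - a2) / denom
    return p


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def synonyms():
    return load_default_synonyms()


CORE_GENES = ["psbA", "psbD", "rbcL", "atpA", "atpB", "petA", "psaA", "psaB"]
MARINE_UNIQUE = ["ycf34", "ycf35", "ycf37", "ycf46", "grx", "pbsA"]


def make_inventory(species_id, genes, total_bp=10000, gc=30.0):
    stats = GenomeStats(
        total_bp=total_bp,
        gc_percent=gc,
        n_cds=len(genes),
        n_trna=30,
        n_rrna=3,
        n_introns=1,
    )
    return GeneInventory(species_id=species_id, gene_set=set(genes), stats=stats)


@pytest.fixture()
def three_genome_matrix():
    """The three-genome comparison: one marine genome carrying six extra
    genes, two freshwater genomes sharing one gene the marine one lacks."""
    inventories = [
        make_inventory("Palmaria palmata", CORE_GENES + MARINE_UNIQUE),
        make_inventory("Kumanoa americana", CORE_GENES + ["ycf91"]),
        make_inventory("Thorea hispida", CORE_GENES + ["ycf91"]),
    ]
    habitat = {
        "Palmaria palmata": "marine",
        "Kumanoa americana": "freshwater",
        "Thorea hispida": "freshwater",
    }
    return build_matrix(inventories, habitat)
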