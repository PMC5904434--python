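"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own code paths (and scikit-bio
where it backs the implementation): patristic distances walk parent chains,
Robinson-Foulds enumerates bipartitions, UniFrac accounts branches with
explicit per-branch tip sets.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from placefrag.model_io import MultipleAlignment, ReferenceTree
from placefrag.synthetic import ScenarioConfig, simulate_reference


@pytest.fixture
def small_tree() -> ReferenceTree:
    return ReferenceTree.from_newick("((A:1,B:2):0.5,C:3);")


def random_tree(n_tips: int, rng: np.random.Generator) -> ReferenceTree:
    """Random topology with exponential branch lengths (test helper)."""
    from placefrag.synthetic import _random_topology

    t = _random_topology(n_tips, rng)
    for node in t.postorder(include_self=True):
        if not node.is_root():
            node.length = float(rng.exponential(0.5)) + 1e-3
    return ReferenceTree(t)


@pytest.fixture
def small_reference():
    """A small simulated reference (tree, alignment, taxonomy, config)."""
    config = ScenarioConfig(n_tips=30, seed=1234)
    tree, alignment, taxonomy = simulate_reference(config)
    return tree, alignment, taxonomy, config


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def oracle_path_length(tree: ReferenceTree, name_a: str, name_b: str) -> float:
    """Patristic distance by explicit parent-chain walk."""
    node_a = tree.find_tip(name_a)
    node_b = tree.find_tip(name_b)
    return oracle_node_distance(node_a, node_b)


def oracle_node_distance(node_a, node_b) -> float:
    anc_a = {}
    d = 0.0
    n = node_a
    while n is not None:
        anc_a[id(n)] = d
        d += n.length or 0.0
        n = n.parent
    d = 0.0
    n = node_b
    while id(n) not in anc_a:
        d += n.length or 0.0
        n = n.parent
    return d + anc_a[id(n)]


def oracle_splits(tree: ReferenceTree) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, canonicalized by their min-label side."""
    all_tips = tree.tip_set
    splits = set()
    for node in tree.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(min(side, other, key=sorted))
    return splits


def oracle_rf(tree_a: ReferenceTree, tree_b: ReferenceTree) -> int:
    return len(oracle_splits(tree_a) ^ oracle_splits(tree_b))


def oracle_unifrac_pair(tree: ReferenceTree, obs_i: set[str], obs_j: set[str]) -> float:
    """Unweighted UniFrac for one sample pair via explicit per-branch tip sets."""
    both = obs_i | obs_j
    unique = 0.0
    total = 0.0
    for node in tree.edges():
        below = (
            {node.name} if node.is_tip() else {t.name for t in node.tips()}
        )
        seen = below & both
        if not seen:
            continue
        if seen == both:  # root-ward of the pair's LCA: shared by construction
            continue
        total += node.length
        in_i = bool(below & obs_i)
        in_j = bool(below & obs_j)
        if in_i != in_j:
            unique += node.length
    return unique / total if total else 0.0


def all_five_tip_topologies() -> list[ReferenceTree]:
    """All 15 labeled unrooted binary topologies on tips A..E."""
    labels = ["A", "B", "C", "D", "E"]
    trees = []
    # each unrooted 5-tip tree is a quartet topology plus the 5th tip on one
    # of its 5 edges; enumerate instead as the 15 distinct sibling choices:
    # pick the two cherries {x,y}, {z,w} of the caterpillar around the middle
    for pair1 in itertools.combinations(labels, 2):
        rest = [l for l in labels if l not in pair1]
        for pair2 in itertools.combinations(rest, 2):
            if pair1[0] > pair2[0]:
                continue  # avoid double-counting the two cherries
            middle = [l for l in rest if l not in pair2][0]
            nwk = (
                f"(({pair1[0]}:1,{pair1[1]}:1):1,{middle}:1,"
                f"({pair2[0]}:1,{pair2[1]}:1):1);"
            )
            trees.append(ReferenceTree.from_newick(nwk))
    assert len(trees) == 15
    return trees


def random_alignment(
    rng: np.random.Generator, n_rows: int, n_cols: int, gap_frac: float = 0.2
) -> MultipleAlignment:
    bases = np.array(list("ACGT-"))
    probs = [(1 - gap_frac) / 4] * 4 + [gap_frac]
    rows = {
        f"R{i:03d}": "".join(rng.choice(bases, size=n_cols, p=probs))
        for i in range(n_rows)
    }
    return MultipleAlignment(rows=rows, n_columns=n_cols)
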