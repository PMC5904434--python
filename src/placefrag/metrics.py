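"""Tree- and placement-quality metrics.

Includes patristic distance matrices, the insertion-error measure used to
benchmark fragment placement (distance from the attachment point to either
the lowest common ancestor of a fragment's true origins or the nearest
origin), tip-to-tip Pearson correlation between trees, unrooted
Robinson-Foulds distance, and per-rank phylogenetic diversity.

The insertion error is measured from the *junction* (the point on the
reference edge where the fragment attaches), not the fragment tip itself:
pendant branches are always positive, and a fragment attached on the correct
branch should be able to score an error of zero.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
from scipy.stats import pearsonr
from skbio import DistanceMatrix

from .errors import (
    IdentifierError,
    InsufficientOverlapError,
    PlacefragError,
    UndefinedCorrelationError,
)
from .model_io import ReferenceTree, Taxonomy
from .placement import strip_tips


def patristic_distances(
    tree: ReferenceTree, tips: Iterable[str] | None = None
) -> DistanceMatrix:
    """All-pairs tip-to-tip path lengths (sum of branch lengths)."""
    if tips is None:
        endpoints = sorted(tree.tip_set)
    else:
        endpoints = sorted(tips)
        unknown = set(endpoints) - tree.tip_set
        if unknown:
            raise IdentifierError(f"unknown tips: {sorted(unknown)[:5]}")
    return tree.tree.tip_tip_distances(endpoints=endpoints)


def insertion_error(
    extended_tree: ReferenceTree,
    fragment_tip_label: str,
    true_origins: Iterable[str],
    variant: str = "lca",
) -> float:
    """Branch-length distance from a grafted fragment's junction to its truth.

    ``variant="lca"`` measures to the lowest common ancestor of all true
    origins (for an unambiguous fragment, the origin tip itself);
    ``variant="min"`` measures to the nearest single origin.  Both variants
    coincide for unambiguous fragments, and ``min <= lca`` always.
    """
    origins = sorted(set(true_origins))
    if not origins:
        raise PlacefragError("true_origins is empty")
    if variant not in ("lca", "min"):
        raise ValueError(f"unknown variant {variant!r}")
    tip = extended_tree.find_tip(fragment_tip_label)
    junction = tip.parent
    origin_nodes = [extended_tree.find_tip(o) for o in origins]
    if variant == "min":
        return min(junction.distance(o) for o in origin_nodes)
    if len(origin_nodes) == 1:
        target = origin_nodes[0]
    else:
        target = extended_tree.tree.lca(origin_nodes)
    return junction.distance(target)


def tip_to_tip_correlation(tree_a: ReferenceTree, tree_b: ReferenceTree) -> float:
    """Pearson r of paired patristic distances over tips shared by both trees."""
    shared = sorted(tree_a.tip_set & tree_b.tip_set)
    if len(shared) < 3:
        raise InsufficientOverlapError(
            f"only {len(shared)} shared tips; need at least 3"
        )
    da = tree_a.tree.tip_tip_distances(endpoints=shared).condensed_form()
    db = tree_b.tree.tip_tip_distances(endpoints=shared).condensed_form()
    if np.allclose(da, da[0]) or np.allclose(db, db[0]):
        raise UndefinedCorrelationError("zero variance in a distance vector")
    return float(pearsonr(da, db).statistic)


def robinson_foulds(tree_a: ReferenceTree, tree_b: ReferenceTree) -> int:
    """Unrooted Robinson-Foulds distance on the shared tip set.

    Both trees are first restricted to their shared tips; the distance is the
    number of non-trivial bipartitions present in exactly one tree.
    """
    shared = tree_a.tip_set & tree_b.tip_set
    if len(shared) < 4:
        warnings.warn("fewer than 4 shared tips; RF distance is trivially 0")
        return 0
    a = tree_a if tree_a.tip_set == shared else strip_tips(tree_a, shared)
    b = tree_b if tree_b.tip_set == shared else strip_tips(tree_b, shared)
    return int(a.tree.compare_rfd(b.tree, rooted=False))


def rank_diversity(
    tree: ReferenceTree, taxonomy: Taxonomy
) -> dict[str, float]:
    """Mean over clades of the maximal within-clade tip-to-tip distance, per rank.

    A clade at a rank is the set of tips sharing the same complete lineage
    prefix down to that rank (exact string match; tips with missing ranks are
    excluded).  Clades with fewer than two tips carry no distance and are
    skipped; a rank with no measurable clade is omitted with a warning.
    """
    covered = sorted(t for t in tree.tip_set if t in taxonomy.lineages)
    if len(covered) < 2:
        raise PlacefragError("taxonomy covers fewer than 2 tree tips")
    dm = patristic_distances(tree, covered)
    pos = {t: i for i, t in enumerate(dm.ids)}
    out: dict[str, float] = {}
    for depth, rank in enumerate(taxonomy.ranks, start=1):
        clades: dict[tuple[str, ...], list[str]] = {}
        for t in covered:
            prefix = taxonomy.lineage_prefix(t, depth)
            if prefix is not None:
                clades.setdefault(prefix, []).append(t)
        maxima = []
        for members in clades.values():
            if len(members) < 2:
                continue
            idx = [pos[m] for m in members]
            maxima.append(float(dm.data[np.ix_(idx, idx)].max()))
        if not maxima:
            warnings.warn(f"rank {rank!r} has no clade with >= 2 tips; omitted")
            continue
        out[rank] = float(np.mean(maxima))
    return out
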