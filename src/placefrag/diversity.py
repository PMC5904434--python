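"""Unweighted UniFrac beta diversity, PCoA, and a cluster-separation score.

These are the pieces needed to demonstrate (and quantify) the long-branch
clustering artifact: presence/absence phylogenetic distances between samples,
their principal-coordinate ordination, and a silhouette-style score of how
strongly a sample grouping separates in the distance matrix.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.ordination import OrdinationResults
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .errors import IdentifierError, PlacefragError
from .model_io import CountTable, ReferenceTree


def unweighted_unifrac(table: CountTable, tree: ReferenceTree) -> DistanceMatrix:
    """Pairwise unweighted UniFrac distances between samples.

    For each sample pair the distance is the branch length leading to tips
    present in exactly one of the two samples, divided by the branch length
    leading to tips present in either.  Branches are counted only up to the
    lowest common ancestor of the pair's observed tips (root-ward branches
    subtending every observed tip are shared by construction and excluded),
    so the distance does not depend on where above that ancestor the tree is
    rooted.  Counts are reduced to presence/absence (count >= 1).
    """
    features = table.feature_ids
    unknown = set(features) - tree.tip_set
    if unknown:
        raise IdentifierError(
            f"features without a tree tip: {sorted(unknown)[:5]}"
        )
    presence = table.presence().values.astype(bool)  # samples x features
    empty = ~presence.any(axis=1)
    if empty.any():
        bad = [table.sample_ids[i] for i in np.flatnonzero(empty)]
        raise PlacefragError(f"samples with zero features: {bad[:5]}")
    # edge x feature incidence: does the edge's subtree contain the feature tip
    feat_pos = {f: j for j, f in enumerate(features)}
    edges = tree.edges()
    n_edges = len(edges)
    incidence = np.zeros((n_edges, len(features)), dtype=bool)
    memo: dict[int, np.ndarray] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            row = np.zeros(len(features), dtype=bool)
            j = feat_pos.get(node.name)
            if j is not None:
                row[j] = True
        else:
            row = np.zeros(len(features), dtype=bool)
            for c in node.children:
                row |= memo[id(c)]
        memo[id(node)] = row
        if not node.is_root():
            incidence[node.edge_num] = row
    lengths = np.array([e.length for e in edges])
    # per-sample: number of observed tips under each edge
    counts = incidence.astype(np.int64) @ presence.T.astype(np.int64)  # edges x samples
    totals = presence.sum(axis=1)  # observed tips per sample
    n = presence.shape[0]
    data = np.zeros((n, n))
    for i in range(n):
        ci = counts[:, i]
        for j in range(i + 1, n):
            cj = counts[:, j]
            observed = (ci + cj) > 0
            above_lca = (ci == totals[i]) & (cj == totals[j])
            keep = observed & ~above_lca
            denom = lengths[keep].sum()
            if denom == 0.0:
                d = 0.0
            else:
                unique = keep & ((ci > 0) ^ (cj > 0))
                d = lengths[unique].sum() / denom
            data[i, j] = data[j, i] = d
    return DistanceMatrix(data, ids=table.sample_ids)


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResults:
    """Classical metric scaling (principal-coordinate analysis).

    Squared distances are double-centered and eigendecomposed; coordinates
    are scaled by the square roots of the non-negative eigenvalues.  Requests
    for more axes than the matrix rank are truncated with a warning.
    """
    max_axes = dm.shape[0] - 1
    if n_axes is not None and n_axes > max_axes:
        warnings.warn(
            f"requested {n_axes} axes exceeds rank bound {max_axes}; truncated"
        )
        n_axes = max_axes
    kwargs = {} if n_axes is None else {"dimensions": n_axes}
    try:
        return _skbio_pcoa(dm, **kwargs)
    except TypeError:  # older scikit-bio spelling
        kwargs = {} if n_axes is None else {"number_of_dimensions": n_axes}
        return _skbio_pcoa(dm, **kwargs)


def cluster_separation(dm: DistanceMatrix, labels: Sequence[str]) -> float:
    """Mean silhouette score of a sample grouping under a distance matrix.

    Ranges over [-1, 1]: near 1 for tight well-separated groups, near 0 when
    the grouping is unrelated to the distances.  Requires at least two groups
    with at least two samples each.
    """
    labels = list(labels)
    if len(labels) != dm.shape[0]:
        raise PlacefragError("one label per sample is required")
    groups = pd.Series(labels).value_counts()
    if len(groups) < 2 or (groups < 2).any():
        raise PlacefragError(
            "cluster_separation needs >= 2 groups with >= 2 samples each"
        )
    from sklearn.metrics import silhouette_score

    return float(silhouette_score(dm.data, labels, metric="precomputed"))


def rarefy(table: CountTable, depth: int, seed: int | np.random.Generator = 0) -> CountTable:
    """Subsample each sample without replacement to an even depth.

    Samples with fewer than ``depth`` total counts are dropped with a
    warning, mirroring standard rarefaction practice.
    """
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    rows = {}
    dropped = []
    for sid in table.sample_ids:
        counts = table.data.loc[sid].values
        total = int(counts.sum())
        if total < depth:
            dropped.append(sid)
            continue
        rows[sid] = rng.multivariate_hypergeometric(counts, depth)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} samples below depth {depth}")
    if not rows:
        raise PlacefragError("no sample reaches the rarefaction depth")
    return CountTable(
        pd.DataFrame.from_dict(rows, orient="index", columns=table.feature_ids)
    )
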