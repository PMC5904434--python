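"""Divide-and-conquer placement of fragments into a reference phylogeny.

The engine mirrors the architecture of ensemble placement tools: the
reference tree is recursively bisected into bounded-size *placement subsets*,
each further bisected into *alignment subsets*; every alignment subset gets a
position-specific scoring profile built from its induced sub-alignment.  A
query fragment is aligned against every profile, assigned to the best-scoring
subset (or rejected when it scores no better than background), and then
attached to the maximum-likelihood branch of its placement subset under a
Jukes-Cantor model with fixed reference branch lengths.  The attachment point
(distal position on the edge) and the new pendant branch length are optimized
by bounded one-dimensional searches; the pendant length is always positive.

Profile scoring and per-edge likelihoods are this package's own
re-implementation of the divide-and-conquer placement idea; they are not
bit-compatible with HMMER/pplacer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from skbio import TreeNode

from .errors import (
    CoverageError,
    EdgeReferenceError,
    IdentifierError,
    InvariantViolationError,
    PlacefragError,
)
from .fragments import Fragment, FragmentSet
from .model_io import MultipleAlignment, Placement, ReferenceTree

#: Sentinel returned by :func:`assign_subset` for fragments that score below
#: the rejection threshold against every profile.
REJECTED = object()

_BASE_TO_INT = {"A": 0, "C": 1, "G": 2, "T": 3, "-": -1, "N": -2}
MIN_PENDANT = 1e-6
MAX_PENDANT = 5.0
_OPT_TOL = 1e-4  # branch-length units, both distal and pendant searches


@dataclass
class DecompositionConfig:
    """Size bounds and rejection threshold for the tree decomposition.

    Defaults mirror the reference configuration used throughout the
    evaluation: placement subsets of at most 5,000 tips, alignment subsets of
    at most 1,000 tips.  ``rejection_threshold`` is a per-position log-odds
    score (nats); fragments whose best profile score falls below it are
    rejected as unrelated to the reference.
    """

    max_placement_subset: int = 5000
    max_alignment_subset: int = 1000
    rejection_threshold: float = 0.0
    occupancy_threshold: float = 0.5  # max gap fraction for a match column
    gap_penalty: float = 6.0  # per-gap-position penalty in the profile DP

    def __post_init__(self) -> None:
        if self.max_alignment_subset > self.max_placement_subset:
            raise ValueError("max_alignment_subset must be <= max_placement_subset")
        if self.max_alignment_subset < 2 or self.max_placement_subset < 2:
            raise ValueError("subset size bounds must be >= 2")


@dataclass
class Profile:
    """Position-specific log-odds profile over the match columns of a sub-alignment."""

    match_columns: np.ndarray  # 0-based original column indices, shape (M,)
    emissions: np.ndarray  # (M, 4), rows sum to 1
    background: np.ndarray  # (4,)
    log_odds: np.ndarray = field(init=False)  # (M, 4)

    def __post_init__(self) -> None:
        if len(self.match_columns) == 0:
            raise InvariantViolationError("profile has no match columns")
        self.log_odds = np.log(self.emissions) - np.log(self.background)[None, :]


@dataclass
class AlignmentSubset:
    id: int
    tips: frozenset[str]
    profile: Profile


@dataclass
class PlacementSubset:
    id: int
    tips: frozenset[str]
    alignment_subsets: list[AlignmentSubset]


@dataclass
class SubsetDecomposition:
    placement_subsets: list[PlacementSubset]

    @property
    def alignment_subsets(self) -> list[AlignmentSubset]:
        return [a for ps in self.placement_subsets for a in ps.alignment_subsets]

    def placement_subset_of(self, alignment_subset_id: int) -> PlacementSubset:
        for ps in self.placement_subsets:
            for a in ps.alignment_subsets:
                if a.id == alignment_subset_id:
                    return ps
        raise KeyError(alignment_subset_id)


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_TO_INT[c] for c in seq), dtype=np.int8, count=len(seq))


def build_profile(
    sub_alignment: MultipleAlignment, occupancy_threshold: float = 0.5
) -> Profile:
    """Column frequencies with add-one pseudocounts over sufficiently occupied columns.

    Columns whose gap fraction exceeds ``occupancy_threshold`` are treated as
    insert columns and excluded.  ``N`` characters contribute to occupancy but
    not to base counts.
    """
    if len(sub_alignment) == 0:
        raise PlacefragError("cannot build a profile from an empty alignment")
    arr = np.vstack([_encode(s) for s in sub_alignment.rows.values()])
    counts = np.stack([(arr == b).sum(axis=0) for b in range(4)], axis=1).astype(float)
    gap_frac = (arr == -1).mean(axis=0)
    match = gap_frac <= occupancy_threshold
    if not match.any():
        raise InvariantViolationError("no column satisfies the occupancy threshold")
    m_counts = counts[match]
    emissions = (m_counts + 1.0) / (m_counts.sum(axis=1, keepdims=True) + 4.0)
    total = counts.sum(axis=0)
    background = (total + 1.0) / (total.sum() + 4.0)
    return Profile(
        match_columns=np.flatnonzero(match),
        emissions=emissions,
        background=background,
    )


def align_to_profile(
    sequence: str, profile: Profile, gap_penalty: float = 6.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """Glocal dynamic-programming alignment of a fragment against a profile.

    Flanking profile columns are skipped for free; internal gaps (in either
    the fragment or the profile) cost ``gap_penalty`` per position; matches
    score the per-column log-odds of the fragment base versus background
    (``N`` scores 0).

    Returns
    -------
    score : float
        Total alignment score (nats).
    frag_pos, columns : ndarray
        Parallel arrays mapping matched fragment positions to original
        alignment column indices.
    """
    enc = _encode(sequence)
    L = len(enc)
    M = len(profile.match_columns)
    lo = np.zeros((L, M))
    valid = enc >= 0
    lo[valid] = profile.log_odds[:, enc[valid]].T
    g = gap_penalty
    S = np.empty((L + 1, M + 1))
    S[0, :] = 0.0  # free leading deletions
    j_pen = g * np.arange(M + 1)
    for i in range(1, L + 1):
        diag = S[i - 1, :-1] + lo[i - 1]
        up = S[i - 1, 1:] - g
        best = np.maximum(diag, up)
        full = np.concatenate(([S[i - 1, 0] - g], best))
        # chained deletions via running max of (score + g*j) - g*j
        S[i] = np.maximum.accumulate(full + j_pen) - j_pen
    j = int(np.argmax(S[L]))
    score = float(S[L, j])
    # traceback (ties prefer match, then fragment insertion, then deletion)
    frag_pos: list[int] = []
    cols: list[int] = []
    i = L
    tol = 1e-6
    while i > 0:
        if j > 0 and abs(S[i, j] - (S[i - 1, j - 1] + lo[i - 1, j - 1])) <= tol:
            frag_pos.append(i - 1)
            cols.append(profile.match_columns[j - 1])
            i -= 1
            j -= 1
        elif j == 0 or abs(S[i, j] - (S[i - 1, j] - g)) <= tol:
            i -= 1
        else:
            j -= 1
    return score, np.array(frag_pos[::-1]), np.array(cols[::-1])


# ---------------------------------------------------------------------------
# Tree decomposition
# ---------------------------------------------------------------------------

def _descendant_tips(tree: ReferenceTree) -> dict[int, frozenset[str]]:
    """Per-edge (child-node) descendant tip sets, keyed by edge id."""
    desc: dict[int, frozenset[str]] = {}
    memo: dict[int, frozenset[str]] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            s = frozenset({node.name})
        else:
            s = frozenset().union(*(memo[id(c)] for c in node.children))
        memo[id(node)] = s
        if not node.is_root():
            desc[node.edge_num] = s
    return desc


def _bisect(
    tips: frozenset[str],
    bound: int,
    desc: dict[int, frozenset[str]],
) -> list[frozenset[str]]:
    """Recursive centroid-edge bisection of a tip set down to ``bound``."""
    if len(tips) <= bound:
        return [tips]
    best_key = None
    best_split = None
    half = len(tips) / 2.0
    for edge_id in sorted(desc):
        inter = desc[edge_id] & tips
        if 0 < len(inter) < len(tips):
            key = (abs(len(inter) - half), edge_id)
            if best_key is None or key < best_key:
                best_key = key
                best_split = inter
    if best_split is None:  # pragma: no cover - unreachable for |tips| >= 2
        raise PlacefragError("no edge separates the tip set")
    return _bisect(best_split, bound, desc) + _bisect(tips - best_split, bound, desc)


def decompose_tree(
    tree: ReferenceTree,
    alignment: MultipleAlignment,
    config: DecompositionConfig | None = None,
) -> SubsetDecomposition:
    """Bisect the reference into placement subsets and nested alignment subsets.

    The edge whose removal splits the current tip set most evenly is removed
    recursively until every placement subset respects
    ``config.max_placement_subset``; the same procedure bounds alignment
    subsets within each placement subset.  Every alignment subset receives a
    profile built from its induced sub-alignment.
    """
    config = config or DecompositionConfig()
    missing = tree.tip_set - set(alignment.rows)
    if missing:
        raise CoverageError(f"tips missing from alignment: {sorted(missing)[:5]}")
    desc = _descendant_tips(tree)
    placement_subsets = []
    aid = 0
    for pid, p_tips in enumerate(_bisect(tree.tip_set, config.max_placement_subset, desc)):
        aligns = []
        for a_tips in _bisect(p_tips, config.max_alignment_subset, desc):
            profile = build_profile(
                alignment.subset(sorted(a_tips)), config.occupancy_threshold
            )
            aligns.append(AlignmentSubset(id=aid, tips=a_tips, profile=profile))
            aid += 1
        placement_subsets.append(
            PlacementSubset(id=pid, tips=p_tips, alignment_subsets=aligns)
        )
    return SubsetDecomposition(placement_subsets=placement_subsets)


def assign_subset(
    fragment: Fragment,
    decomposition: SubsetDecomposition,
    rejection_threshold: float = 0.0,
    gap_penalty: float = 6.0,
):
    """Rank alignment subsets by per-position profile log-odds score.

    Returns a list of ``(alignment_subset_id, score)`` sorted by descending
    score (ties broken toward the smaller subset id), or the module-level
    :data:`REJECTED` sentinel when even the best score falls below
    ``rejection_threshold`` — i.e. the fragment matches no subset better than
    background composition.
    """
    scored = []
    L = max(len(fragment.sequence), 1)
    for sub in decomposition.alignment_subsets:
        total, _, _ = align_to_profile(fragment.sequence, sub.profile, gap_penalty)
        scored.append((sub.id, total / L))
    scored.sort(key=lambda t: (-t[1], t[0]))
    if not scored or scored[0][1] < rejection_threshold:
        return REJECTED
    return scored


# ---------------------------------------------------------------------------
# Jukes-Cantor likelihood machinery
# ---------------------------------------------------------------------------

def _jc_decay(t) -> np.ndarray | float:
    return np.exp(-4.0 * np.asarray(t) / 3.0)


class TreeLikelihood:
    """Per-column conditional likelihoods on a fixed reference tree.

    For every non-root node ``c`` (owning the edge to its parent ``u``) and
    every alignment column, two normalized 4-vectors are cached: ``D[c]``,
    the conditional likelihood of the data below ``c`` given the state at
    ``c``, and ``A[c]``, the prior-weighted likelihood of all data outside
    the subtree of ``c`` given the state at ``u``.  Attaching a fragment at
    distance ``d`` above ``c`` on an edge of length ``t`` then costs one
    Jukes-Cantor transform of each vector (``d`` and ``t - d`` respectively),
    which makes per-edge likelihood surfaces cheap to evaluate.

    Vectors are renormalized to sum to one at every step; only likelihood
    ratios between candidate attachments are ever compared, so the dropped
    scaling constants are shared by all candidates.
    """

    def __init__(self, tree: ReferenceTree, alignment: MultipleAlignment):
        missing = tree.tip_set - set(alignment.rows)
        if missing:
            raise CoverageError(f"tips missing from alignment: {sorted(missing)[:5]}")
        self.tree = tree
        n_cols = alignment.n_columns
        nodes = list(tree.tree.postorder(include_self=True))
        self._index = {id(n): i for i, n in enumerate(nodes)}
        self._nodes = nodes
        n = len(nodes)
        self.lengths = np.array(
            [0.0 if nd.is_root() else nd.length for nd in nodes]
        )
        D = np.empty((n, n_cols, 4))
        msg = np.empty((n, n_cols, 4))  # message from node to its parent
        for i, nd in enumerate(nodes):
            if nd.is_tip():
                enc = _encode(alignment.rows[nd.name])
                vec = np.full((n_cols, 4), 0.25)
                obs = enc >= 0
                vec[obs] = 0.0
                vec[np.flatnonzero(obs), enc[obs]] = 1.0
                D[i] = vec
            else:
                prod = np.ones((n_cols, 4))
                for c in nd.children:
                    prod *= msg[self._index[id(c)]]
                prod /= prod.sum(axis=1, keepdims=True)
                D[i] = prod
            if not nd.is_root():
                x = _jc_decay(nd.length)
                msg[i] = x * D[i] + (1.0 - x) * 0.25
        self.D = D
        self._msg = msg
        # A[c]: outside partial at the parent endpoint of c's edge
        A = np.empty((n, n_cols, 4))
        R = np.empty((n, n_cols, 4))  # outside partial at the node itself
        root = nodes[-1]
        R[self._index[id(root)]] = 0.25
        for nd in tree.tree.preorder(include_self=True):
            i = self._index[id(nd)]
            if not nd.is_root():
                x = _jc_decay(nd.length)
                r = x * A[i] + (1.0 - x) * 0.25
                R[i] = r / r.sum(axis=1, keepdims=True)
            children = nd.children
            if not children:
                continue
            k = len(children)
            idxs = [self._index[id(c)] for c in children]
            # prefix/suffix products of child messages avoid division by zero
            prefix = np.ones((k + 1, n_cols, 4))
            for j in range(k):
                prefix[j + 1] = prefix[j] * msg[idxs[j]]
            suffix = np.ones((k + 1, n_cols, 4))
            for j in range(k - 1, -1, -1):
                suffix[j] = suffix[j + 1] * msg[idxs[j]]
            for j, ci in enumerate(idxs):
                a = R[i] * prefix[j] * suffix[j + 1]
                A[ci] = a / a.sum(axis=1, keepdims=True)
        self.A = A
        self.edge_index = np.array(
            [self._index[id(tree.edge_node(e))] for e in range(tree.n_edges)]
        )

    def node_row(self, edge_id: int) -> int:
        return int(self.edge_index[edge_id])


def _attachment_posterior(Dx: np.ndarray, Ux: np.ndarray, bases: np.ndarray):
    """Posterior mass of each fragment base at the attachment point.

    ``Dx`` and ``Ux`` are the distal/proximal partials transformed to the
    attachment point, shape ``(..., C, 4)``; ``bases`` are the fragment base
    indices per column.  Returns ``fhat`` of shape ``(..., C)``.
    """
    f = Dx * Ux
    fs = f.sum(axis=-1)
    fb = np.take_along_axis(f, bases.reshape((1,) * (f.ndim - 2) + (-1, 1)), axis=-1)[
        ..., 0
    ]
    return fb / fs


def _pendant_scores(fhat: np.ndarray, pendant) -> np.ndarray:
    """Relative log-likelihood of the fragment for given pendant length(s)."""
    xp = _jc_decay(pendant)
    return np.log(0.25 + (fhat - 0.25) * xp).sum(axis=-1)


def _optimal_pendant(fhat: np.ndarray) -> tuple[float, float]:
    """Maximize the pendant score in closed-ish form.

    With ``x = exp(-4p/3)`` the per-column contribution is
    ``log(0.25 + c_i x)`` with ``c_i = fhat_i - 0.25``; the derivative in
    ``x`` is monotone decreasing, so the optimum is found by bisection on the
    derivative sign within the pendant bounds.
    """
    c = fhat - 0.25
    x_lo = math.exp(-4.0 * MAX_PENDANT / 3.0)
    x_hi = math.exp(-4.0 * MIN_PENDANT / 3.0)

    def deriv(x: float) -> float:
        return float((c / (0.25 + c * x)).sum())

    if deriv(x_hi) >= 0.0:
        x = x_hi
    elif deriv(x_lo) <= 0.0:
        x = x_lo
    else:
        lo, hi = x_lo, x_hi
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            if deriv(mid) > 0.0:
                lo = mid
            else:
                hi = mid
        x = 0.5 * (lo + hi)
    p = min(max(-0.75 * math.log(x), MIN_PENDANT), MAX_PENDANT)
    return p, float(_pendant_scores(fhat, p))


def place_fragment(
    fragment_id: str,
    columns: np.ndarray,
    bases: np.ndarray,
    likelihood: TreeLikelihood,
    candidate_edges: Sequence[int],
    subset_id: int | None = None,
    n_refine: int = 5,
) -> Placement:
    """Maximum-likelihood attachment of an aligned fragment to one edge.

    ``columns``/``bases`` give the fragment's aligned reference columns and
    base indices (gap-free, ``N`` excluded).  All candidate edges are scanned
    with a mid-edge attachment and a fixed starting pendant; the ``n_refine``
    best are then optimized over distal position (bounded to the edge) and
    pendant length (bounded below by :data:`MIN_PENDANT`, so every placement
    has a strictly positive pendant branch).  Candidate attachments at the
    exact edge endpoints are evaluated explicitly and win ties, so an exact
    duplicate of a reference sequence attaches at distal 0 of its terminal
    edge.  Remaining ties break toward the smallest edge id.
    """
    if len(columns) == 0:
        raise PlacefragError(f"fragment {fragment_id!r} aligned to no columns")
    cand = np.asarray(sorted(candidate_edges), dtype=int)
    rows = likelihood.edge_index[cand]
    Dc = likelihood.D[rows][:, columns, :]
    Ac = likelihood.A[rows][:, columns, :]
    t = likelihood.lengths[rows]
    # vectorized mid-edge scan
    xd = _jc_decay(t / 2.0)[:, None, None]
    Dx = xd * Dc + (1.0 - xd) * 0.25
    Ux = xd * Ac + (1.0 - xd) * 0.25  # same decay: t - t/2 = t/2
    fhat = _attachment_posterior(Dx, Ux, bases)
    scan = _pendant_scores(fhat, 0.05)
    order = np.lexsort((cand, -scan))
    best = None
    for k in order[: max(1, n_refine)]:
        Dk, Ak, tk = Dc[k], Ac[k], float(t[k])

        def fhat_at(d: float) -> np.ndarray:
            xd = _jc_decay(d)
            xu = _jc_decay(tk - d)
            return _attachment_posterior(
                xd * Dk + (1 - xd) * 0.25, xu * Ak + (1 - xu) * 0.25, bases
            )

        def best_pendant(d: float) -> tuple[float, float]:
            return _optimal_pendant(fhat_at(d))

        d = tk / 2.0
        p, score = best_pendant(d)
        for _ in range(2):
            if tk > 0:
                res = minimize_scalar(
                    lambda dd: -_pendant_scores(fhat_at(dd), p),
                    bounds=(0.0, tk),
                    method="bounded",
                    options={"xatol": _OPT_TOL},
                )
                d = float(res.x)
            p, score = best_pendant(d)
        # snap to edge endpoints when they do at least as well
        for d_end in (0.0, tk):
            p_end, s_end = best_pendant(d_end)
            if s_end >= score - 1e-9:
                d, p, score = d_end, p_end, s_end
                break
        key = (-score, int(cand[k]))
        if best is None or key < best[0]:
            best = (key, int(cand[k]), d, p, score)
    _, edge_id, d, p, score = best
    return Placement(
        fragment_id=fragment_id,
        edge_id=edge_id,
        distal_length=d,
        pendant_length=p,
        score=score / max(len(columns), 1),
        subset_id=subset_id,
    )


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

def _candidate_edges(tree: ReferenceTree, tips: frozenset[str]) -> list[int]:
    """Edges spanned by a tip set, plus the stem edge above its LCA."""
    desc = _descendant_tips(tree)
    edges = [
        e
        for e, dset in desc.items()
        if (dset & tips) and not tips.issubset(dset)
    ]
    # stem edge above the LCA of the subset (smallest superset of tips)
    lca_edges = [e for e, dset in desc.items() if tips.issubset(dset)]
    if lca_edges:
        stem = min(lca_edges, key=lambda e: len(desc[e]))
        edges.append(stem)
    return sorted(set(edges))


class PlacementEngine:
    """Decomposition, profiles and likelihood caches bundled for repeated queries."""

    def __init__(
        self,
        tree: ReferenceTree,
        alignment: MultipleAlignment,
        config: DecompositionConfig | None = None,
    ):
        self.tree = tree
        self.alignment = alignment
        self.config = config or DecompositionConfig()
        self.decomposition = decompose_tree(tree, alignment, self.config)
        self.likelihood = TreeLikelihood(tree, alignment)
        self._profiles = {a.id: a for a in self.decomposition.alignment_subsets}
        self._candidates = {
            ps.id: _candidate_edges(tree, ps.tips)
            for ps in self.decomposition.placement_subsets
        }
        self._subset_of = {
            a.id: ps for ps in self.decomposition.placement_subsets
            for a in ps.alignment_subsets
        }

    def place(self, fragment: Fragment) -> Placement | None:
        """Place one fragment; returns None when the fragment is rejected."""
        ranked = assign_subset(
            fragment,
            self.decomposition,
            self.config.rejection_threshold,
            self.config.gap_penalty,
        )
        if ranked is REJECTED:
            return None
        aid = ranked[0][0]
        sub = self._profiles[aid]
        _, frag_pos, cols = align_to_profile(
            fragment.sequence, sub.profile, self.config.gap_penalty
        )
        enc = _encode(fragment.sequence)
        keep = enc[frag_pos] >= 0  # drop N positions
        cols = cols[keep]
        bases = enc[frag_pos[keep]].astype(int)
        ps = self._subset_of[aid]
        return place_fragment(
            fragment.id,
            cols,
            bases,
            self.likelihood,
            self._candidates[ps.id],
            subset_id=aid,
        )

    def place_all(
        self, fragments: Iterable[Fragment]
    ) -> tuple[list[Placement], list[str]]:
        placements, rejected = [], []
        for frag in fragments:
            plc = self.place(frag)
            if plc is None:
                rejected.append(frag.id)
            else:
                placements.append(plc)
        return placements, rejected


def insert_all(
    fragments: FragmentSet | Iterable[Fragment],
    tree: ReferenceTree,
    alignment: MultipleAlignment,
    config: DecompositionConfig | None = None,
) -> tuple[list[Placement], list[str]]:
    """Place every fragment; returns ``(placements, rejected_fragment_ids)``.

    Deterministic given inputs and configuration: subsets, profile scores and
    per-edge likelihood optimizations involve no randomness, and all ties
    break toward smaller identifiers.
    """
    engine = PlacementEngine(tree, alignment, config)
    return engine.place_all(fragments)


# ---------------------------------------------------------------------------
# Tree surgery
# ---------------------------------------------------------------------------

def graft_placements(
    tree: ReferenceTree, placements: Sequence[Placement]
) -> ReferenceTree:
    """Attach each placement as a new tip; existing tip-to-tip paths are unchanged.

    Multiple placements on one edge are attached in order of increasing
    distal length (ties by fragment id).  Raises
    :class:`EdgeReferenceError` when a distal position exceeds its edge.
    """
    new = tree.copy()
    existing = set(new.tip_set)
    by_edge: dict[int, list[Placement]] = {}
    for plc in placements:
        node = tree.edge_node(plc.edge_id)  # validates edge id on the original
        if plc.distal_length < 0 or plc.distal_length > node.length + 1e-12:
            raise EdgeReferenceError(
                f"distal {plc.distal_length} exceeds edge {plc.edge_id} "
                f"(length {node.length})"
            )
        if plc.fragment_id in existing:
            raise IdentifierError(f"fragment id {plc.fragment_id!r} collides with a tip")
        existing.add(plc.fragment_id)
        by_edge.setdefault(plc.edge_id, []).append(plc)
    for edge_id, plcs in sorted(by_edge.items()):
        plcs.sort(key=lambda p: (p.distal_length, p.fragment_id))
        child = new.edge_node(edge_id)
        parent = child.parent
        slot = parent.children.index(child)
        total = child.length
        parent.remove(child)
        below = child
        consumed = 0.0
        for plc in plcs:
            below.length = min(plc.distal_length, total) - consumed
            junction = TreeNode(length=None)
            tip = TreeNode(name=plc.fragment_id, length=plc.pendant_length)
            junction.append(below)
            junction.append(tip)
            below = junction
            consumed = min(plc.distal_length, total)
        below.length = total - consumed
        parent.children.insert(slot, below)
        below.parent = parent
    return ReferenceTree(new.tree)


def strip_tips(tree: ReferenceTree, keep: Iterable[str]) -> ReferenceTree:
    """Induced subtree on ``keep``; suppressed degree-2 nodes sum their lengths."""
    keep = set(keep)
    unknown = keep - tree.tip_set
    if unknown:
        raise IdentifierError(f"tips not in tree: {sorted(unknown)[:5]}")
    if len(keep) < 2:
        raise IdentifierError("strip_tips requires at least 2 tips to keep")
    return ReferenceTree(tree.tree.shear(keep))
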