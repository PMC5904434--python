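"""Evaluation drivers: train/test splits, reinsertion error profiling,
mutation-robustness series, method comparison, and the beta-diversity
long-branch demonstration.

The drivers produce long-format :class:`pandas.DataFrame` tables (one row per
fragment/iteration/method) so downstream summaries and plots stay simple.
All randomness flows from explicit seeds; per-iteration seeds derive from a
master seed by iteration index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress, mannwhitneyu
from skbio import DistanceMatrix
from skbio.tree import nj

from .diversity import cluster_separation, unweighted_unifrac
from .errors import PlacefragError
from .fragments import Fragment, FragmentSet, classify_fragment, extract_fragments
from .metrics import insertion_error, robinson_foulds, tip_to_tip_correlation
from .model_io import CountTable, MultipleAlignment, Placement, ReferenceTree
from .placement import (
    DecompositionConfig,
    PlacementEngine,
    graft_placements,
    insert_all,
    strip_tips,
)
from . import synthetic


@dataclass
class SplitSpec:
    """Fraction of fragments withheld for reinsertion, with seed and iterations."""

    fraction: float = 0.05
    seed: int = 0
    iterations: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise PlacefragError("fraction must be in (0, 1)")


def _iteration_rng(master_seed: int, iteration: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([master_seed, iteration]))


def _mutation_path(
    sequence: str,
    k_max: int,
    rng: np.random.Generator,
    forbidden: frozenset[str],
    max_tries: int = 1000,
) -> list[str]:
    """Nested series of mutants: element ``k`` is ``sequence`` with the first
    ``k`` steps of a random non-revisiting mutation path applied."""
    bases = "ACGT"
    for _ in range(max_tries):
        positions = rng.choice(len(sequence), size=k_max, replace=False)
        offsets = rng.integers(1, 4, size=k_max)
        path = [sequence]
        chars = list(sequence)
        for pos, off in zip(positions, offsets):
            old = chars[pos]
            base_idx = bases.index(old) if old in bases else int(rng.integers(4))
            chars[pos] = bases[(base_idx + int(off)) % 4]
            path.append("".join(chars))
        if not any(p in forbidden for p in path[1:]):
            return path
    raise PlacefragError("could not draw a novel mutation path")


@dataclass
class SplitResult:
    training_tree: ReferenceTree
    training_alignment: MultipleAlignment
    testing_fragments: list[Fragment]
    gold_tree: ReferenceTree  # tips renamed to fragment ids
    selected_origin: dict[str, str]  # fragment id -> the origin kept as truth


def split_reference(
    tree: ReferenceTree,
    alignment: MultipleAlignment,
    fragments: FragmentSet,
    spec: SplitSpec,
    iteration: int = 0,
) -> SplitResult:
    """Withhold a random fraction of fragments and strip their origins.

    The training tree/alignment lose every origin of every withheld fragment;
    the testing gold standard is the full tree stripped to one origin per
    withheld fragment (the lexicographically smallest, for determinism) with
    tips renamed to fragment ids so gold, insertion and de novo trees share a
    namespace.
    """
    rng = _iteration_rng(spec.seed, iteration)
    frags = sorted(fragments, key=lambda f: f.id)
    n_withhold = max(1, int(round(spec.fraction * len(frags))))
    chosen_idx = rng.choice(len(frags), size=n_withhold, replace=False)
    chosen = [frags[i] for i in sorted(chosen_idx)]
    withheld_origins = frozenset().union(*(f.origins for f in chosen))
    keep = tree.tip_set - withheld_origins
    if len(keep) < 2:
        raise PlacefragError("split would remove nearly all tips")
    training_tree = strip_tips(tree, keep)
    training_alignment = alignment.subset(sorted(keep))
    selected = {f.id: min(f.origins) for f in chosen}
    gold = strip_tips(tree, set(selected.values())).copy()
    rename = {origin: fid for fid, origin in selected.items()}
    for tip in gold.tree.tips():
        tip.name = rename[tip.name]
    gold = ReferenceTree(gold.tree)
    return SplitResult(
        training_tree=training_tree,
        training_alignment=training_alignment,
        testing_fragments=chosen,
        gold_tree=gold,
        selected_origin=selected,
    )


def lift_placement(
    placement: Placement, training_tree: ReferenceTree, full_tree: ReferenceTree
) -> Placement:
    """Map a placement on a stripped tree onto the corresponding full-tree edge.

    Every edge of the stripped tree corresponds to a path in the full tree of
    exactly the same length (suppressed nodes sum their branch lengths), so
    the attachment point transfers uniquely: walk rootward from the full-tree
    node matching the training edge's child until the distal offset is
    consumed.
    """
    child = training_tree.edge_node(placement.edge_id)
    tips_below = (
        {child.name} if child.is_tip() else {t.name for t in child.tips()}
    )
    if len(tips_below) == 1:
        node = full_tree.find_tip(next(iter(tips_below)))
    else:
        node = full_tree.tree.lca([full_tree.find_tip(t) for t in tips_below])
    remaining = placement.distal_length
    while remaining > node.length + 1e-12 and not node.parent.is_root():
        remaining -= node.length
        node = node.parent
    return Placement(
        fragment_id=placement.fragment_id,
        edge_id=node.edge_num,
        distal_length=min(remaining, node.length),
        pendant_length=placement.pendant_length,
        score=placement.score,
        subset_id=placement.subset_id,
    )


def _error_rows(
    extended: ReferenceTree,
    fragments: Iterable[Fragment],
    placed_ids: set[str],
    representative_ids: frozenset[str],
    iteration: int,
    method: str,
) -> list[dict]:
    rows = []
    for frag in fragments:
        cls = classify_fragment(frag, representative_ids)
        row = {
            "iteration": iteration,
            "fragment_id": frag.id,
            "ambiguity": frag.ambiguity,
            "ambiguity_bin": cls.ambiguity_bin,
            "representative_only": cls.representative_only,
            "k": 0,
            "method": method,
        }
        if frag.id in placed_ids:
            row["error_lca"] = insertion_error(extended, frag.id, frag.origins, "lca")
            row["error_min"] = insertion_error(extended, frag.id, frag.origins, "min")
            row["rejected"] = False
        else:
            row["error_lca"] = np.nan
            row["error_min"] = np.nan
            row["rejected"] = True
        rows.append(row)
    return rows


def run_reinsertion(
    tree: ReferenceTree,
    alignment: MultipleAlignment,
    fragments: FragmentSet,
    config: DecompositionConfig | None = None,
    withhold: SplitSpec | None = None,
    representative_ids: frozenset[str] | None = None,
) -> pd.DataFrame:
    """Place fragments (into the full or a training tree) and score errors.

    Without withholding, every fragment is reinserted into the unmodified
    reference and its error measured in place.  With a split, the withheld
    fragments are placed into the training tree and their placements lifted
    back onto the full tree so the error to the (stripped-away) true origins
    remains measurable.  Errors use both the LCA and minimum-distance
    variants; rejected fragments get NaN errors and a flag.
    """
    representative_ids = representative_ids or tree.tip_set
    if withhold is None:
        engine = PlacementEngine(tree, alignment, config)
        placements, _rejected = engine.place_all(fragments)
        extended = graft_placements(tree, placements)
        rows = _error_rows(
            extended, fragments, {p.fragment_id for p in placements},
            representative_ids, 0, "insertion",
        )
        return pd.DataFrame(rows)
    all_rows = []
    for it in range(withhold.iterations):
        split = split_reference(tree, alignment, fragments, withhold, it)
        engine = PlacementEngine(split.training_tree, split.training_alignment, config)
        placements, _rejected = engine.place_all(split.testing_fragments)
        lifted = [
            lift_placement(p, split.training_tree, tree) for p in placements
        ]
        extended = graft_placements(tree, lifted)
        all_rows.extend(
            _error_rows(
                extended, split.testing_fragments,
                {p.fragment_id for p in placements},
                representative_ids, it, "insertion",
            )
        )
    return pd.DataFrame(all_rows)


def run_mutation_series(
    tree: ReferenceTree,
    alignment: MultipleAlignment,
    fragments: Sequence[Fragment],
    k_max: int = 10,
    replicates: int = 5,
    seed: int = 0,
    config: DecompositionConfig | None = None,
) -> pd.DataFrame:
    """Reinsert increasingly mutated copies of unambiguous fragments.

    Mutations accumulate sequentially: for each fragment and replicate a
    random path of ``k_max`` point mutations is drawn (one position at a
    time, never revisiting a position, each to a different base), and the
    ``k``-mutant applies the first ``k`` steps.  Every mutant therefore has
    Hamming distance exactly ``k`` from the original, the ``k``-series of
    one fragment is nested, and no mutant collides with an existing fragment
    sequence (the whole path is redrawn on collision).  ``k = 0`` reproduces
    the plain reinsertion baseline.
    """
    fragments = list(fragments)
    if any(f.ambiguity != 1 for f in fragments):
        raise PlacefragError("mutation series requires unambiguous fragments")
    engine = PlacementEngine(tree, alignment, config)
    forbidden = frozenset(f.sequence for f in fragments)
    rows = []
    for rep in range(replicates):
        rng = _iteration_rng(seed, rep)
        paths = {
            frag.id: _mutation_path(frag.sequence, k_max, rng, forbidden)
            for frag in fragments
        }
        for k in range(k_max + 1):
            batch = []
            for frag in fragments:
                batch.append(
                    Fragment(
                        id=f"{frag.id}~k{k}r{rep}",
                        sequence=paths[frag.id][k],
                        origins=frag.origins,
                    )
                )
            placements, rejected = engine.place_all(batch)
            extended = graft_placements(tree, placements)
            placed = {p.fragment_id for p in placements}
            for frag in batch:
                err = (
                    insertion_error(extended, frag.id, frag.origins, "min")
                    if frag.id in placed
                    else np.nan
                )
                rows.append(
                    {
                        "iteration": rep,
                        "fragment_id": frag.id.split("~")[0],
                        "k": k,
                        "error": err,
                        "rejected": frag.id not in placed,
                        "method": "insertion",
                    }
                )
    return pd.DataFrame(rows)


def mutation_summary(series: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-k mean error and the least-squares slope of mean error versus k."""
    means = series.dropna(subset=["error"]).groupby("k")["error"].mean()
    fit = linregress(means.index.values.astype(float), means.values)
    return means, float(fit.slope)


def compare_methods(
    iterations: Sequence[tuple[ReferenceTree, Mapping[str, ReferenceTree]]],
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Per-iteration tree distances to gold, plus Mann-Whitney p per metric.

    Each item pairs a gold-standard tree with candidate trees by label.  For
    every candidate the tip-to-tip Pearson correlation and Robinson-Foulds
    distance to gold are computed; with exactly two candidate labels and more
    than one iteration, a two-sided Mann-Whitney test compares the two
    labels' distributions for each metric.
    """
    rows = []
    for it, (gold, candidates) in enumerate(iterations):
        if len(candidates) < 2:
            raise PlacefragError("compare_methods needs >= 2 candidate labels")
        for label, cand in candidates.items():
            rows.append(
                {
                    "iteration": it,
                    "method": label,
                    "tip2tip_r": tip_to_tip_correlation(cand, gold),
                    "rf": robinson_foulds(cand, gold),
                }
            )
    df = pd.DataFrame(rows)
    labels = sorted(df["method"].unique())
    pvalues: dict[str, float | None] = {}
    if df["iteration"].nunique() < 2:
        warnings.warn("single iteration: p-values omitted")
        return df, {"tip2tip_r": None, "rf": None}
    if len(labels) == 2:
        a, b = labels
        for metric in ("tip2tip_r", "rf"):
            x = df.loc[df["method"] == a, metric].values.astype(float)
            y = df.loc[df["method"] == b, metric].values.astype(float)
            if np.ptp(np.concatenate([x, y])) == 0.0:
                pvalues[metric] = 1.0  # identical distributions
            else:
                pvalues[metric] = float(
                    mannwhitneyu(x, y, alternative="two-sided").pvalue
                )
    return df, pvalues


def denovo_fragment_tree(fragments: Iterable[Fragment]) -> ReferenceTree:
    """Distance-based reconstruction from fragment sequences (de novo stand-in).

    Pairwise Hamming mismatch fractions are Jukes-Cantor corrected (capped
    just below saturation) and fed to neighbor joining.  This is a deliberate
    stand-in for an external aligner+ML pipeline, adequate as the de novo
    comparator in self-contained experiments.
    """
    frags = sorted(fragments, key=lambda f: f.id)
    if len(frags) < 3:
        raise PlacefragError("de novo reconstruction needs >= 3 fragments")
    L = len(frags[0].sequence)
    arr = np.vstack(
        [np.frombuffer(f.sequence.encode(), dtype=np.uint8) for f in frags]
    )
    p = (arr[:, None, :] != arr[None, :, :]).mean(axis=2)
    p = np.minimum(p, 0.7499)  # just below the JC saturation bound of 3/4
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(d, 0.0)
    dm = DistanceMatrix(d, ids=[f.id for f in frags])
    tree = nj(dm, neg_as_zero=True)
    return ReferenceTree(tree)


def run_split_comparison(
    tree: ReferenceTree,
    alignment: MultipleAlignment,
    fragments: FragmentSet,
    spec: SplitSpec,
    config: DecompositionConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, float | None]]:
    """Insertion versus de novo trees against the gold standard, per iteration.

    For each iteration: split, place the withheld fragments into the training
    tree, graft, strip to the fragment tips (the insertion tree); build the
    de novo stand-in from the same fragments; compare both to the gold
    standard via tip-to-tip correlation and Robinson-Foulds.
    """
    triples = []
    for it in range(spec.iterations):
        split = split_reference(tree, alignment, fragments, spec, it)
        engine = PlacementEngine(split.training_tree, split.training_alignment, config)
        placements, rejected = engine.place_all(split.testing_fragments)
        if rejected:
            warnings.warn(f"iteration {it}: {len(rejected)} fragments rejected")
        extended = graft_placements(split.training_tree, placements)
        insertion = strip_tips(extended, [p.fragment_id for p in placements])
        denovo = denovo_fragment_tree(split.testing_fragments)
        triples.append((split.gold_tree, {"denovo": denovo, "insertion": insertion}))
    return compare_methods(triples)


def aggregate_to_fragments(table: CountTable, fragments: FragmentSet) -> CountTable:
    """Collapse a tip-level count table to fragment features (sum over origins)."""
    data = {}
    for frag in fragments:
        cols = [o for o in sorted(frag.origins) if o in table.data.columns]
        if cols:
            data[frag.id] = table.data[cols].sum(axis=1)
    return CountTable(pd.DataFrame(data, index=table.data.index))


def run_beta_diversity_artifact(
    preset: str,
    seed: int = 0,
    config: DecompositionConfig | None = None,
    **scenario_overrides,
) -> dict[str, float]:
    """End-to-end long-branch artifact experiment on a synthetic survey.

    Builds the scenario, extracts fragments, constructs both a de novo
    fragment tree and an insertion tree (fragments grafted into the curated
    reference), computes unweighted UniFrac on the fragment-level table under
    each tree, and scores carrier/non-carrier cluster separation.  A long-stem
    outgroup should separate strongly under the de novo tree and weakly under
    the insertion tree; a short stem should separate under neither.
    """
    sc = synthetic.build_scenario(preset, seed, **scenario_overrides)
    if config is None:
        # desk-scale analog of the reference decomposition: enough subsets
        # that a diverged clade gets its own profile instead of drowning in
        # an ingroup consensus
        n = sc.tree.n_tips
        config = DecompositionConfig(
            max_placement_subset=max(10, n // 2),
            max_alignment_subset=max(4, n // 20),
        )
    lo, hi = sc.config.window
    fragments = extract_fragments(sc.alignment, lo, hi, sc.config.target_len)
    frag_table = aggregate_to_fragments(sc.table, fragments)
    labels = synthetic.carrier_labels(sc.table)
    denovo = denovo_fragment_tree(fragments)
    placements, rejected = insert_all(fragments, sc.tree, sc.alignment, config)
    if rejected:
        warnings.warn(f"{len(rejected)} fragments rejected during insertion")
        keep = [f for f in frag_table.feature_ids if f not in set(rejected)]
        frag_table = CountTable(frag_table.data[keep])
    insertion = graft_placements(sc.tree, placements)
    out = {}
    for label, tr in (("denovo", denovo), ("insertion", insertion)):
        dm = unweighted_unifrac(frag_table, tr)
        out[label] = cluster_separation(dm, labels)
    return out
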