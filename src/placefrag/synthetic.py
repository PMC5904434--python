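"""Synthetic references, alignments and count tables for self-contained testing.

The generator emulates, at desk scale, the structure of a large curated 16S
reference: a rooted tree with branch lengths (rescaled so the mean tip-to-root
distance is ~1, the scale reported for real references), ungapped sequences
evolved along it under Jukes-Cantor, a V4-like column window from which
fragments retain phylogenetic signal, a nested two-rank taxonomy cut from the
clade structure, and presence/absence study tables in which a rare,
long-branch outgroup clade (the analog of a handful of low-abundance archaeal
sOTUs in a bacterial survey) is carried by only a subset of samples.

Branch lengths are in substitutions/site scaled by ``mutation_scale``; the
outgroup's stem evolves at ``rate_multiplier`` times the nominal rate, so the
reference tree records a modest stem branch while the outgroup *sequences*
are far more diverged than any ingroup pair — the regime in which short
fragments saturate and de novo reconstructions inflate the branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import PlacefragError
from .model_io import CountTable, MultipleAlignment, ReferenceTree, Taxonomy

_BASES = "ACGT"


@dataclass
class OutgroupConfig:
    """A small, highly diverged clade attached to the reference on a stem branch."""

    present: bool = False
    stem_branch_length: float = 0.5
    n_outgroup_tips: int = 3
    rate_multiplier: float = 40.0  # window-specific acceleration on the stem
    carrier_sample_fraction: float = 0.5
    abundance: int = 2  # per-carrier count of each outgroup feature


@dataclass
class ScenarioConfig:
    """Study conditions for a synthetic reference and survey.

    ``window`` is 1-based with exclusive end; defaults carve a 150-nt
    fragment window out of a 400-column full-length analog.  ``depth`` is the
    per-sample sequencing depth for the multinomial count tables; ingroup
    feature abundances span three orders of magnitude (log-uniform), so the
    rarest features flicker in and out of presence — the realistic noise
    floor against which the outgroup artifact is judged.
    """

    n_tips: int = 150
    birth_rate: float = 1.0
    seq_length: int = 400
    window: tuple[int, int] = (126, 276)
    target_len: int = 150
    mutation_scale: float = 0.3
    n_samples: int = 60
    depth: int = 400
    seed: int = 0
    outgroup: OutgroupConfig = field(default_factory=OutgroupConfig)

    def __post_init__(self) -> None:
        if self.n_tips < 4:
            raise PlacefragError("n_tips must be >= 4")
        lo, hi = self.window
        if not (1 <= lo < hi <= self.seq_length + 1):
            raise PlacefragError("window must lie within the sequence length")


def _rng_for(config: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _random_topology(n_tips: int, rng: np.random.Generator) -> TreeNode:
    """Random bifurcating topology grown by uniform tip splitting."""
    root = TreeNode()
    root.extend([TreeNode(), TreeNode()])
    tips = list(root.children)
    while len(tips) < n_tips:
        victim = tips.pop(int(rng.integers(len(tips))))
        victim.extend([TreeNode(), TreeNode()])
        tips.extend(victim.children)
    for i, tip in enumerate(root.tips()):
        tip.name = f"T{i + 1:04d}"
    return root


def _evolve(seq: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """One Jukes-Cantor step: substitution probability 3/4(1 - e^{-4t/3})."""
    p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    hit = rng.random(len(seq)) < p
    out = seq.copy()
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq)


def simulate_reference(
    config: ScenarioConfig,
) -> tuple[ReferenceTree, MultipleAlignment, Taxonomy]:
    """Random birth-style tree, sequences evolved along it, two-rank taxonomy.

    Branch lengths are iid exponential with mean ``1/birth_rate``, then
    rescaled so the mean tip-to-root distance is 1.  Sequence evolution uses
    branch length times ``mutation_scale`` substitutions/site.  Taxonomy
    ranks ("phylum", "genus") are assigned by cutting the tree at 25% and 60%
    of the maximum root-to-tip depth, which guarantees multi-tip clades.
    """
    rng = _rng_for(config, 0)
    tree = _random_topology(config.n_tips, rng)
    for node in tree.postorder(include_self=True):
        if not node.is_root():
            node.length = float(rng.exponential(1.0 / config.birth_rate))
    depths = [t.accumulate_to_ancestor(tree) for t in tree.tips()]
    scale = float(np.mean(depths))
    for node in tree.postorder(include_self=True):
        if not node.is_root():
            node.length /= scale

    root_seq = rng.integers(0, 4, size=config.seq_length)
    seqs: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = _evolve(seq, child.length * config.mutation_scale, rng)
            if child.is_tip():
                seqs[child.name] = child_seq
            else:
                descend(child, child_seq)

    descend(tree, root_seq)
    alignment = MultipleAlignment(
        rows={name: _decode(s) for name, s in seqs.items()},
        n_columns=config.seq_length,
    )
    alignment.root_sequence = root_seq  # ancestral anchor for implant_outgroup
    taxonomy = _taxonomy_from_depth_cuts(tree, cuts=(0.25, 0.60))
    return ReferenceTree(tree), alignment, taxonomy


def _taxonomy_from_depth_cuts(
    tree: TreeNode, cuts: tuple[float, ...]
) -> Taxonomy:
    max_depth = max(t.accumulate_to_ancestor(tree) for t in tree.tips())
    rank_names = ("phylum", "genus")[: len(cuts)]
    labels: dict[str, list[str]] = {t.name: [] for t in tree.tips()}
    for ci, cut in enumerate(cuts):
        threshold = cut * max_depth
        clade_ids: dict[int, int] = {}
        prefix = rank_names[ci][0]
        # depth-first: the shallowest node past the threshold defines the clade
        def walk(node: TreeNode, depth: float, clade: int | None) -> None:
            if clade is None and (depth >= threshold or node.is_tip()):
                clade = clade_ids.setdefault(id(node), len(clade_ids) + 1)
            if node.is_tip():
                labels[node.name].append(
                    f"{prefix}{clade}" if clade is not None else ""
                )
                return
            for child in node.children:
                walk(child, depth + child.length, clade)

        walk(tree, 0.0, None)
    return Taxonomy(
        lineages={t: tuple(v) for t, v in labels.items()}, ranks=rank_names
    )


def implant_outgroup(
    tree: ReferenceTree,
    alignment: MultipleAlignment,
    config: ScenarioConfig,
) -> tuple[ReferenceTree, MultipleAlignment]:
    """Attach a small diverged clade to the root via a stem branch.

    The new root has the previous ingroup as one child (zero-length stub) and
    the outgroup clade on a stem of exactly ``stem_branch_length``.  Outgroup
    sequences evolve along the stem at ``rate_multiplier`` times the nominal
    rate, then diversify over short internal branches; with the default long
    stem they are far more diverged than the reference tree's branch lengths
    alone suggest.  Returns the inputs unchanged when the outgroup is absent.
    """
    og = config.outgroup
    if not og.present or og.n_outgroup_tips == 0:
        return tree, alignment
    rng = _rng_for(config, 1)
    old_root = tree.tree
    ancestor = getattr(alignment, "root_sequence", None)
    if ancestor is None:
        # column-majority consensus as an ancestral proxy for externally
        # supplied alignments
        arr = np.vstack(
            [
                np.fromiter((_BASES.index(c) for c in s), dtype=np.int8)
                for s in alignment.rows.values()
            ]
        )
        ancestor = np.array(
            [np.bincount(col, minlength=4).argmax() for col in arr.T],
            dtype=np.int64,
        )
    stem_div = og.stem_branch_length * og.rate_multiplier * config.mutation_scale
    og_root_seq = _evolve(np.asarray(ancestor, dtype=np.int64), stem_div, rng)
    og_clade = (
        _random_topology(og.n_outgroup_tips, rng)
        if og.n_outgroup_tips >= 2
        else TreeNode(name="tmp")
    )
    rows = dict(alignment.rows)
    if og.n_outgroup_tips == 1:
        og_clade.name = "OG01"
        rows["OG01"] = _decode(og_root_seq)
    else:
        for node in og_clade.postorder(include_self=False):
            # bounded short internal edges: the clade is a recent radiation
            node.length = float(rng.uniform(0.01, 0.05))
        for i, tip in enumerate(og_clade.tips()):
            tip.name = f"OG{i + 1:02d}"
        og_seqs: dict[str, np.ndarray] = {}

        # acceleration applies to the deep stem only; the clade's own recent
        # radiation evolves at the nominal rate
        def descend(node: TreeNode, seq: np.ndarray) -> None:
            for child in node.children:
                cs = _evolve(seq, child.length * config.mutation_scale, rng)
                if child.is_tip():
                    og_seqs[child.name] = cs
                else:
                    descend(child, cs)

        descend(og_clade, og_root_seq)
        for name, s in og_seqs.items():
            rows[name] = _decode(s)
    og_clade.length = og.stem_branch_length
    old_root.length = 0.0
    new_root = TreeNode()
    new_root.append(old_root)
    new_root.append(og_clade)
    return (
        ReferenceTree(new_root),
        MultipleAlignment(rows=rows, n_columns=alignment.n_columns),
    )


def outgroup_tip_names(tree: ReferenceTree) -> list[str]:
    return [t for t in tree.tip_names if t.startswith("OG")]


def simulate_study(tree: ReferenceTree, config: ScenarioConfig) -> CountTable:
    """Two latent sample groups differing only in carriage of the outgroup.

    Ingroup features share a log-uniform abundance profile (three orders of
    magnitude) and are multinomially sampled to ``depth`` per sample, so the
    groups are exchangeable on the ingroup.  Carrier samples additionally
    contain every outgroup feature at the configured low count; non-carriers
    lack them entirely.
    """
    rng = _rng_for(config, 2)
    og = config.outgroup
    og_tips = outgroup_tip_names(tree)
    ingroup = [t for t in tree.tip_names if not t.startswith("OG")]
    profile = 10.0 ** rng.uniform(0.0, 3.0, size=len(ingroup))
    probs = profile / profile.sum()
    n_carriers = int(round(og.carrier_sample_fraction * config.n_samples)) if og_tips else 0
    carrier_flags = np.zeros(config.n_samples, dtype=bool)
    carrier_flags[:n_carriers] = True
    carrier_flags = rng.permutation(carrier_flags)
    rows = {}
    for i in range(config.n_samples):
        sid = f"S{i + 1:03d}"
        counts = rng.multinomial(config.depth, probs)
        og_counts = [og.abundance if carrier_flags[i] else 0] * len(og_tips)
        rows[sid] = np.concatenate([counts, og_counts]).astype(int)
    return CountTable(
        pd.DataFrame.from_dict(rows, orient="index", columns=ingroup + og_tips)
    )


def carrier_labels(table: CountTable, og_tips: Iterable[str] | None = None) -> list[str]:
    """Label each sample 'carrier'/'noncarrier' by outgroup feature presence."""
    og = [f for f in table.feature_ids if f.startswith("OG")] if og_tips is None else list(og_tips)
    og = [f for f in og if f in table.feature_ids]
    if not og:
        return ["noncarrier"] * len(table.sample_ids)
    present = (table.data[og] > 0).any(axis=1)
    return ["carrier" if p else "noncarrier" for p in present]


_PRESETS = {
    "plain": dict(outgroup=OutgroupConfig(present=False)),
    "longbranch": dict(outgroup=OutgroupConfig(present=True, stem_branch_length=0.5)),
    "shortbranch": dict(outgroup=OutgroupConfig(present=True, stem_branch_length=0.005)),
}


def scenario_config(preset: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Named study conditions: 'plain', 'longbranch', or 'shortbranch'."""
    if preset not in _PRESETS:
        raise PlacefragError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    kwargs = dict(_PRESETS[preset])
    kwargs.update(overrides)
    return ScenarioConfig(seed=seed, **kwargs)


@dataclass
class Scenario:
    config: ScenarioConfig
    tree: ReferenceTree
    alignment: MultipleAlignment
    taxonomy: Taxonomy
    table: CountTable


def build_scenario(preset: str, seed: int = 0, **overrides) -> Scenario:
    """Generate tree + alignment (+ outgroup) + taxonomy + study table."""
    config = scenario_config(preset, seed, **overrides)
    tree, alignment, taxonomy = simulate_reference(config)
    tree, alignment = implant_outgroup(tree, alignment, config)
    table = simulate_study(tree, config)
    return Scenario(
        config=config, tree=tree, alignment=alignment, taxonomy=taxonomy, table=table
    )
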