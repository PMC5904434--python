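"""Insertion trees versus de novo fragment trees against a gold standard.

Withholds 5% of fragments from a synthetic reference over several
iterations, reinserts them into the reduced tree, reconstructs a de novo
tree from the fragments alone, and compares both to the stripped true tree
by tip-to-tip Pearson correlation and Robinson-Foulds distance, with a
two-sided Mann-Whitney test across iterations.
"""

from placefrag.experiments import SplitSpec, run_split_comparison
from placefrag.fragments import extract_fragments
from placefrag.synthetic import ScenarioConfig, simulate_reference

config = ScenarioConfig(n_tips=120, seed=21)
tree, alignment, _ = simulate_reference(config)
fragments = extract_fragments(alignment, *config.window, config.target_len)

table, pvals = run_split_comparison(
    tree, alignment, fragments,
    SplitSpec(fraction=0.05, seed=21, iterations=8),
)
summary = table.groupby("method")[["tip2tip_r", "rf"]].mean()
print(summary.round(4))
print(f"Mann-Whitney two-sided p (tip-to-tip r): {pvals['tip2tip_r']:.3g}")
print(f"Mann-Whitney two-sided p (RF):           {pvals['rf']:.3g}")
# Insertion trees inherit the curated branch lengths of the reference, so
# their distances to the gold standard are consistently tighter than those
# of a tree estimated from 150-nt fragments alone.
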