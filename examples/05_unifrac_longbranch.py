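"""The long-branch beta-diversity artifact, reproduced and resolved.

A synthetic survey carries three rare, deeply diverged outgroup features in
half of its samples.  Under a de novo tree built from the 150-nt fragments
their saturated distances become one huge branch, and unweighted UniFrac
splits the samples into spurious carrier/non-carrier clusters; placing the
same fragments into the curated reference instead makes the clusters
disappear.  A short-stem (recently diverged) outgroup shows the artifact
under neither tree.
"""

import warnings

from placefrag.experiments import run_beta_diversity_artifact

warnings.simplefilter("ignore")
for preset in ("longbranch", "shortbranch"):
    result = run_beta_diversity_artifact(preset, seed=1)
    print(f"{preset:12s} carrier-separation silhouette: "
          f"de novo tree {result['denovo']:+.3f}   "
          f"insertion tree {result['insertion']:+.3f}")
# Silhouette near 0 means the carrier grouping does not structure the
# distances; values above ~0.5 indicate strong (here: spurious) clustering.
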