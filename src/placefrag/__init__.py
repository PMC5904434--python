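"""placefrag: phylogenetic placement of short amplicon fragments into
reference trees, with the evaluation harness to judge placement quality.

The library covers the full workflow: slicing fixed-length fragments out of
a gapped reference alignment window, dereplicating them with origin
tracking, dividing a reference phylogeny into bounded-size subsets with
per-subset sequence profiles, attaching fragments to maximum-likelihood
branches, grafting the placements into an extended tree, and measuring the
result (insertion error, tip-to-tip correlation, Robinson-Foulds, unweighted
UniFrac and PCoA), plus synthetic data generators so everything is testable
without external downloads.
"""

from .errors import PlacefragError
from .fragments import (
    Fragment,
    FragmentSet,
    classify_fragment,
    extract_fragments,
    mutate_fragment,
)
from .model_io import (
    CountTable,
    MultipleAlignment,
    Placement,
    ReferenceTree,
    Taxonomy,
    read_alignment,
    read_jplace,
    read_taxonomy,
    write_jplace,
)
from .placement import (
    REJECTED,
    DecompositionConfig,
    PlacementEngine,
    Profile,
    SubsetDecomposition,
    assign_subset,
    build_profile,
    decompose_tree,
    graft_placements,
    insert_all,
    place_fragment,
    strip_tips,
)
from .metrics import (
    insertion_error,
    patristic_distances,
    rank_diversity,
    robinson_foulds,
    tip_to_tip_correlation,
)
from .diversity import cluster_separation, pcoa, rarefy, unweighted_unifrac
from .experiments import (
    SplitSpec,
    compare_methods,
    denovo_fragment_tree,
    run_beta_diversity_artifact,
    run_mutation_series,
    run_reinsertion,
    run_split_comparison,
    split_reference,
)
from . import synthetic

__version__ = "0.1.0"


def read_tree(path) -> ReferenceTree:
    """Read a newick file into a :class:`ReferenceTree` with stable edge ids."""
    return ReferenceTree.read(path)
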