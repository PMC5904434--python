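# Methods

`placefrag` implements phylogenetic placement of short, fixed-length
amplicon fragments (sOTUs/exact sequence variants) into a large curated
reference phylogeny, together with the evaluation machinery needed to judge
placement quality: fragment generation from an alignment window,
train/test splits, insertion-error metrics, tree-to-tree comparisons,
mutation-robustness series, and the unweighted-UniFrac demonstration of the
long-branch clustering artifact that motivates insertion trees in the first
place.

## Fragment generation

Fragments are the degapped slices of a gapped reference alignment over a
fixed column window (the in-silico analog of an amplified variable region
such as 16S V4).  Windows are addressed 1-based with an exclusive end, so a
window `(2263, 3794)` spans 1,531 columns.  Slices shorter than the target
length (default 150 nt) are discarded; longer slices are trimmed to their
first 150 characters.  Surviving sequences are dereplicated literally
(an `N` never merges with a base), and each unique fragment keeps the set of
reference identifiers it came from — its *ambiguity*.  Origins of
duplicates merge as a set union with no first-seen priority, and fragment
identifiers are assigned in lexicographic sequence order, which makes
extraction independent of the input row order.  The bookkeeping identities
`n_kept = n_input − n_too_short` and `n_unique = n_kept − n_duplicates`
are structural and tested as such.

## Placement engine

The engine follows the divide-and-conquer architecture of
ensemble-of-HMMs placement tools, re-implemented from first principles (it
is not bit-compatible with HMMER/pplacer):

1. **Decomposition.** The reference tree is recursively bisected by the
   *centroid edge* — the edge whose removal splits the current tip set most
   evenly (ties to the smallest edge id) — until every *placement subset*
   has at most `max_placement_subset` tips (default 5,000, the reference
   configuration); each placement subset is further bisected into
   *alignment subsets* of at most `max_alignment_subset` tips (default
   1,000).  Both levels partition the tips exactly.

2. **Profiles.** Every alignment subset gets a position-specific profile
   over its induced sub-alignment: columns with a gap fraction at most the
   occupancy threshold (default 0.5) become match columns; emissions are
   column base frequencies with add-one pseudocounts; the background is the
   subset's overall composition.  Fragments are aligned to a profile by
   glocal dynamic programming — free flanking deletions, linear internal
   gap penalty (default 6.0 nats/position), per-column log-odds match
   scores.  The stiff gap penalty is deliberate: gap-majority columns are
   already excluded from the profile, so DP gaps correspond to genuine
   indels against well-occupied columns, and a weaker penalty lets
   log-odds noise shift a fragment's flanking columns by one, which
   corrupts the downstream likelihood far more than it gains in alignment
   score.

3. **Assignment and rejection.** A fragment is scored against every
   profile; subsets are ranked by per-position log-odds (ties toward the
   smaller subset id).  If even the best score is below the rejection
   threshold (default 0.0 — no better than background composition), the
   fragment is rejected as unrelated to the reference.  The threshold is
   this package's own; rejection behavior, not a specific score scale, is
   the contract.

4. **Attachment.** Within the assigned placement subset (its spanned edges
   plus the stem above its LCA), each candidate edge is scored under
   Jukes-Cantor with fixed reference branch lengths.  Two normalized
   conditional-likelihood caches make this cheap: for every edge, the
   partial below its child and the prior-weighted partial for the rest of
   the tree at its parent, per alignment column.  Attaching at distal
   offset `d` with pendant length `p` then costs one JC transform of each
   vector.  All candidate edges are first scanned at mid-edge with a fixed
   starting pendant; the best five are refined by coordinate descent —
   the distal offset by bounded scalar search (tolerance 1e-4
   branch-length units), the pendant in closed-ish form by bisection on
   the monotone derivative of the per-column score.  Edge endpoints are
   evaluated explicitly and win ties, so an exact duplicate of a reference
   sequence attaches at distal 0 of its own terminal edge and scores an
   insertion error of exactly zero.  Pendant lengths are bounded below by
   1e-6, so every placement carries a strictly positive pendant branch.
   Because only likelihood *ratios* between candidate attachments matter,
   all partials are renormalized per column; the dropped constants are
   shared by every candidate.  Scores are reported per aligned column.

5. **Grafting.** Placements become new tips: the edge is subdivided at the
   distal offset and the fragment hangs from the junction on its pendant
   branch.  Multiple placements on one edge attach in order of increasing
   distal offset (ties by fragment id).  Grafting never changes any
   pre-existing tip-to-tip path length, which is tested exactly against a
   brute-force path oracle.

Placement is fully deterministic: no randomness anywhere, and every tie
breaks toward the smallest identifier.

## Metrics and their conventions

* **Insertion error** is measured from the *junction* — the attachment
  point on the reference edge — not from the fragment tip: pendants are
  always positive, so including them would make a perfect placement score
  a nonzero error.  The `lca` variant measures the path to the lowest
  common ancestor of the fragment's true origins (for unambiguous
  fragments, the origin tip); the `min` variant the path to the nearest
  origin.  The two coincide for unambiguous fragments.  The often-quoted
  relationship `min ≤ lca` holds for attachments inside the clade spanned
  by the origins (where real placements land); for an attachment outside
  that clade every path to an origin crosses the LCA, so
  `min = lca + d(LCA, nearest origin)`.  Tests assert that exact case
  split.
* **Tip-to-tip correlation** is the Pearson r of paired patristic
  distances over the tips shared by two trees (pairs with tips missing
  from either tree are omitted); it requires at least 3 shared tips and is
  invariant under uniform rescaling of either tree.
* **Robinson-Foulds** uses the unrooted bipartition convention on the
  shared tip set (both trees are restricted first).  Fewer than four
  shared tips yields a trivial 0 with a warning.
* **Rank diversity** groups tips by exact lineage-prefix match per rank,
  takes the maximal within-clade tip-to-tip distance for clades with at
  least two tips, and averages over clades; unlabeled ranks are excluded
  and empty ranks omitted with a warning.
* **Unweighted UniFrac** divides the branch length leading to tips present
  in exactly one of two samples by the branch length leading to tips
  present in either, with presence meaning count ≥ 1 (optional seeded
  rarefaction is provided).  Branches are counted only up to the LCA of
  the pair's observed tips: every branch root-ward of that point subtends
  all observed tips of both samples and is therefore shared by
  construction, so excluding it makes the distance independent of where
  above the LCA the tree is rooted.  Implementations anchored at the tree
  root differ exactly on those root-ward branches; the test suite
  cross-checks against scikit-bio on instances where the conventions
  coincide and against a per-branch brute-force oracle everywhere.

## Experiment drivers

Train/test splits withhold a random fraction of fragments and strip *all*
of their origins from the tree and alignment; the gold standard is the
full tree stripped to one origin per withheld fragment (lexicographically
smallest, for determinism) with tips renamed to fragment ids so gold,
insertion and de novo trees share a namespace.  When errors must be
measured for fragments whose origins were stripped, the placement on the
training tree is *lifted* onto the full tree: a training edge corresponds
to a full-tree path of exactly the same length, so the attachment point
transfers uniquely.

The mutation-robustness series accumulates point mutations sequentially:
for each fragment and replicate one random mutation path is drawn (one
position at a time, never revisiting a position, each to a different
base), and the `k`-mutant applies the first `k` steps, so every mutant is
at Hamming distance exactly `k` and the series of one fragment is nested.
Nesting couples a fragment's error across `k`, which is both the natural
reading of "mutating 1 to 10 times" and a variance reduction that lets the
mean-error trend be read without independent-draw noise.  Paths colliding
with an existing fragment sequence are redrawn whole.  The standalone
`mutate_fragment` operation instead draws each `k`-mutant independently.

The de novo comparator bundled for self-contained testing is a
neighbor-joining reconstruction from pairwise fragment mismatch fractions
with Jukes-Cantor correction (capped just below the 3/4 saturation bound);
it is a deliberate stand-in for an external aligner+ML pipeline and is
labeled as such.  Method comparisons report per-iteration tip-to-tip
correlation and RF against gold and a two-sided Mann-Whitney test across
iterations (exact for small samples without ties, normal approximation
with tie correction otherwise; identical constant distributions report
p = 1).  Per-iteration seeds derive from the master seed by iteration
index.

## Synthetic study conditions

The generator produces, at desk scale, the structure the experiments
assume: a random bifurcating topology grown by uniform tip splitting with
iid exponential branch lengths, rescaled so the mean tip-to-root distance
is 1 (the scale reported for real curated references); sequences evolved
along the tree under Jukes-Cantor at `mutation_scale` (default 0.3)
substitutions/site per unit branch length; a 150-column fragment window in
a 400-column "full-length" sequence; a two-rank taxonomy cut at 25% and
60% of the maximum depth (guaranteeing multi-tip clades); and
presence/absence survey tables.  Default study sizes: 150 reference tips,
60 samples, sequencing depth 400, ingroup abundances log-uniform over
three orders of magnitude — deep enough that common features are always
seen, shallow enough that rare features flicker in and out of presence,
which is the realistic noise floor against which clustering artifacts must
be judged.

The long-branch scenario implants a three-tip outgroup clade (the analog
of a handful of rare archaeal sOTUs in a bacterial survey) on a stem at
the root.  Reference branch lengths record a modest stem (0.5 in the
`longbranch` preset, 0.005 in `shortbranch`), but the outgroup *sequences*
evolve along the stem at a window-specific rate acceleration (default
40×): hypervariable-region divergence across deep splits far exceeds the
full-length average that curated reference branch lengths reflect.  In the
long preset the outgroup's 150-nt fragments are therefore saturated
(~75% mismatch) against everything, and a distance-based de novo tree
inflates the stem to several times the entire ingroup depth — the regime
in which unweighted UniFrac manufactures carrier/non-carrier clusters.
The short preset models a recently diverged rare clade: its fragments look
like ordinary ingroup members and neither tree separates carriers.  The
outgroup's internal edges are short and bounded (uniform 0.01–0.05,
nominal rate) so the clade is a tight recent radiation, and its ancestor
is the simulation's true root sequence.  Carrier samples contain every
outgroup feature at a fixed low count (default 2); non-carriers lack them;
the ingroup abundance profile is shared, so carriage is the only
systematic group difference.  Cluster separation is scored as the mean
silhouette of the carrier grouping on the UniFrac matrix.  The
artifact-experiment driver scales the decomposition bounds to the tree
(half the tips per placement subset, a twentieth per alignment subset), the
desk-scale analog of the reference configuration's hundreds of subsets —
with a single whole-tree profile a diverged clade would be rejected as
background, which does not happen at real scale.

These defaults were chosen once, by probing that the documented
saturation mechanism (not any particular score) behaves as intended, and
then frozen; the thresholds quoted in the acceptance tests are the
package's own calibration of this synthetic analog, not measurements of
any real data set.

## Evaluation problem sizes

The bundled evaluation (test suite and `scripts/acceptance.py`) runs at
desk scale, chosen so every experiment exercises the full pipeline on one
CPU: metric oracles on all 15 unrooted five-tip topologies plus 200 random
trees of up to 10 tips; exact reinsertion on a 50-tip reference; the
mutation series on 200 fragment series × 5 replicates × k = 0..10
(11,000 placements); the split comparison on a 300-tip reference with 20
iterations of a 5% split; the beta-diversity artifact on the default
150-tip, 60-sample scenario; and bookkeeping on 500 random alignments.
These sizes are the package's own evaluation design; the algorithms
themselves carry no size assumptions beyond memory.

## What the synthetic conditions do and do not show

Passing tests on these conditions demonstrate the algorithmic properties:
metric correctness against brute-force oracles, faithful reinsertion of
known sequences, graceful error growth under point mutations, the
advantage of curated branch lengths over fragment-only reconstruction, and
the tree-dependence of unweighted UniFrac.  They do not emulate amplicon
error profiles, chimeras, denoising artifacts, rate heterogeneity across
sites, alignment uncertainty, or the taxon-sampling biases of real
references; conclusions about any particular real data set require that
data set.

## Numerical choices and degenerate inputs

Jukes-Cantor throughout (uniform base frequencies, no rate heterogeneity);
root prior 1/4.  Optimization tolerances: 1e-4 branch-length units for the
distal search, pendant bisection to machine-level interval width, pendant
bounds [1e-6, 5].  Zero-length edges are legal (the distal search
degenerates to the endpoint).  Missing newick branch lengths read as 0.0
with a warning.  Fragments consisting only of `N`s cannot be placed
(no informative columns).  A placement subset with a single tip places on
its terminal edge.  Trees are treated as rooted at the newick root;
unrooted metrics (RF) work on bipartitions.  jplace edge numbers follow
the `{n}` depth-first postorder convention and `distal_length` is measured
from the edge's child (tipward) node.

## Known limitations

* The profile model is a position-specific log-odds scorer, not a full
  profile HMM with forward scoring; subset ranking and rejection behavior
  are the contract, and on small subsets (fewer than ~10 rows) a
  neighboring clade's tighter profile occasionally outranks the home
  subset (~2–3% of exact fragments at 10-row profiles).
* Likelihood caches are dense per (node × column); references beyond a few
  thousand tips and columns will want sparse or chunked storage.
* The de novo stand-in is distance-based; it is intentionally weaker than
  a modern ML pipeline, and conclusions about the margin over de novo
  methods (not the direction) depend on the comparator.
* Branch lengths of the reference are taken as fixed truth; no re-estimation
  after grafting.
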