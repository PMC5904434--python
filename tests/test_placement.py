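import numpy as np
import pytest

from placefrag.errors import (
    CoverageError,
    EdgeReferenceError,
    IdentifierError,
    PlacefragError,
)
from placefrag.fragments import Fragment, extract_fragments, mutate_fragment
from placefrag.model_io import MultipleAlignment, Placement, ReferenceTree
from placefrag.placement import (
    REJECTED,
    AlignmentSubset,
    DecompositionConfig,
    PlacementEngine,
    PlacementSubset,
    SubsetDecomposition,
    TreeLikelihood,
    assign_subset,
    build_profile,
    decompose_tree,
    graft_placements,
    place_fragment,
    strip_tips,
)
from placefrag.synthetic import ScenarioConfig, simulate_reference

from conftest import oracle_path_length, random_tree

_B = {"A": 0, "C": 1, "G": 2, "T": 3}


class TestDecomposition:
    @pytest.mark.parametrize("seed", range(5))
    def test_partition_at_both_levels(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 30))
        tree = random_tree(n, rng)
        aln = MultipleAlignment(
            rows={t: "ACGTACGT" for t in tree.tip_names}, n_columns=8
        )
        config = DecompositionConfig(max_placement_subset=5, max_alignment_subset=3)
        dec = decompose_tree(tree, aln, config)
        p_tips = [ps.tips for ps in dec.placement_subsets]
        assert all(len(t) <= 5 for t in p_tips)
        assert sorted(x for t in p_tips for x in t) == sorted(tree.tip_names)
        a_tips = [a.tips for a in dec.alignment_subsets]
        assert all(len(t) <= 3 for t in a_tips)
        assert sorted(x for t in a_tips for x in t) == sorted(tree.tip_names)
        for ps in dec.placement_subsets:
            nested = [x for a in ps.alignment_subsets for x in a.tips]
            assert sorted(nested) == sorted(ps.tips)

    def test_loose_bound_gives_single_subset(self, small_reference):
        tree, aln, _, _ = small_reference
        dec = decompose_tree(tree, aln, DecompositionConfig(5000, 1000))
        assert len(dec.placement_subsets) == 1
        assert dec.placement_subsets[0].tips == tree.tip_set

    def test_missing_tip_coverage_error(self, small_reference):
        tree, aln, _, _ = small_reference
        rows = dict(aln.rows)
        rows.popitem()
        short = MultipleAlignment(rows=rows, n_columns=aln.n_columns)
        with pytest.raises(CoverageError):
            decompose_tree(tree, short, DecompositionConfig())


class TestProfile:
    def test_identical_rows_concentrate_emissions(self):
        aln = MultipleAlignment(
            rows={f"r{i}": "ACGTT" for i in range(5)}, n_columns=5
        )
        prof = build_profile(aln)
        assert list(prof.match_columns) == [0, 1, 2, 3, 4]
        for j, base in enumerate("ACGTT"):
            assert prof.emissions[j].argmax() == _B[base]
            assert prof.emissions[j, _B[base]] == pytest.approx(6 / 9)

    def test_gap_heavy_column_is_insert_state(self):
        rows = {"r1": "A-", "r2": "C-", "r3": "G-", "r4": "T-"}
        rows["r1"] = "AA"  # column 1: 3/4 gaps
        prof = build_profile(MultipleAlignment(rows=rows, n_columns=2))
        assert list(prof.match_columns) == [0]

    def test_column_frequencies_with_pseudocounts(self):
        rows = {"r1": "A", "r2": "A", "r3": "C", "r4": "-"}
        prof = build_profile(MultipleAlignment(rows=rows, n_columns=1))
        np.testing.assert_allclose(
            prof.emissions[0], [3 / 7, 2 / 7, 1 / 7, 1 / 7]
        )

    def test_empty_alignment_rejected(self):
        with pytest.raises(PlacefragError):
            build_profile(MultipleAlignment(rows={}, n_columns=0))


class TestAssign:
    def test_exact_slice_ranks_own_subset_first(self):
        # simulation property: across replicates, an exact tip slice almost
        # always scores its own alignment subset highest (profiles are
        # frequency summaries, so a neighboring clade's tighter profile can
        # occasionally nose ahead)
        total, first, top2 = 0, 0, 0
        for seed in range(5):
            config = ScenarioConfig(n_tips=50, seed=seed)
            tree, aln, _ = simulate_reference(config)
            dec = decompose_tree(
                tree, aln, DecompositionConfig(max_placement_subset=25,
                                               max_alignment_subset=10)
            )
            lo, hi = config.window
            frags = extract_fragments(aln, lo, hi, config.target_len)
            subset_of = {t: a.id for a in dec.alignment_subsets for t in a.tips}
            for frag in frags:
                ranked = assign_subset(frag, dec)
                assert ranked is not REJECTED
                own = {subset_of[o] for o in frag.origins}
                total += 1
                first += ranked[0][0] in own
                top2 += any(a in own for a, _ in ranked[:2])
        assert first / total >= 0.95
        assert top2 / total >= 0.99

    def test_uniform_random_sequence_rejected(self, small_reference):
        tree, aln, _, _ = small_reference
        dec = decompose_tree(tree, aln, DecompositionConfig(10, 5))
        rng = np.random.default_rng(99)
        junk = Fragment(
            "junk", "".join(rng.choice(list("ACGT"), size=150)), frozenset({"x"})
        )
        assert assign_subset(junk, dec) is REJECTED

    def test_tie_breaks_to_smaller_subset_id(self):
        rows = {f"r{i}": "ACGTACGTACGT" for i in range(3)}
        aln = MultipleAlignment(rows=rows, n_columns=12)
        prof = build_profile(aln)
        dec = SubsetDecomposition(
            placement_subsets=[
                PlacementSubset(0, frozenset(rows), [
                    AlignmentSubset(0, frozenset(rows), prof),
                    AlignmentSubset(1, frozenset(rows), prof),
                ])
            ]
        )
        frag = Fragment("f", "ACGTACGTACGT", frozenset({"r0"}))
        ranked = assign_subset(frag, dec)
        assert ranked[0][0] == 0
        assert ranked[0][1] == pytest.approx(ranked[1][1])


def _oracle_extend(tree: ReferenceTree, edge_id: int, d: float, p: float):
    """Independent tree surgery: attach 'QUERY' at (edge, distal, pendant)."""
    from skbio import TreeNode

    new = tree.copy()
    child = new.edge_node(edge_id)
    parent = child.parent
    total = child.length
    parent.remove(child)
    child.length = d
    junction = TreeNode(length=total - d)
    tip = TreeNode(name="QUERY", length=p)
    junction.append(child)
    junction.append(tip)
    parent.append(junction)
    return new.tree


def _oracle_loglik(sk_tree, leaf_bases: dict[str, np.ndarray]) -> float:
    """Felsenstein pruning under Jukes-Cantor, independent implementation."""

    def transition(t):
        x = np.exp(-4.0 * t / 3.0)
        return np.full((4, 4), (1 - x) / 4) + np.eye(4) * x

    def partial(node):
        if node.is_tip():
            obs = leaf_bases[node.name]  # (C,) int, -1 for missing
            vec = np.ones((len(obs), 4))
            known = obs >= 0
            vec[known] = 0.0
            vec[np.flatnonzero(known), obs[known]] = 1.0
            return vec
        out = None
        for c in node.children:
            msg = partial(c) @ transition(c.length).T
            out = msg if out is None else out * msg
        return out

    lik = (partial(sk_tree) * 0.25).sum(axis=1)
    return float(np.log(lik).sum())


class TestPlaceFragment:
    @pytest.fixture(scope="class")
    def eight_tip(self):
        config = ScenarioConfig(n_tips=8, seed=77)
        tree, aln, _ = simulate_reference(config)
        return tree, aln, config

    @pytest.mark.parametrize("k", [0, 5, 10])
    def test_agrees_with_exhaustive_grid_oracle(self, eight_tip, k):
        tree, aln, config = eight_tip
        lo, hi = config.window
        cols = np.arange(lo - 1, hi - 1)
        tip = sorted(tree.tip_set)[3]
        seq = aln.rows[tip][lo - 1:hi - 1]
        seq = mutate_fragment(seq, k, rng=k + 1)
        bases = np.array([_B[c] for c in seq])
        lik = TreeLikelihood(tree, aln)
        plc = place_fragment("q", cols, bases, lik,
                             candidate_edges=range(tree.n_edges))
        # oracle: exhaustive (edge x distal x pendant) grid with independent
        # tree surgery and pruning, restricted to the fragment's columns
        leaf_bases = {
            name: np.array([_B[c] for c in row])[cols]
            for name, row in aln.rows.items()
        }
        leaf_bases["QUERY"] = bases
        best = (-np.inf, None)
        for edge_id in range(tree.n_edges):
            t_len = tree.edge_node(edge_id).length
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                for p in (1e-6, 1e-3, 0.01, 0.03, 0.1, 0.3, 1.0):
                    ll = _oracle_loglik(
                        _oracle_extend(tree, edge_id, frac * t_len, p), leaf_bases
                    )
                    if ll > best[0]:
                        best = (ll, edge_id)
        assert plc.edge_id == best[1]
        # the optimized attachment must be at least as good as the grid best
        impl_ll = _oracle_loglik(
            _oracle_extend(tree, plc.edge_id, plc.distal_length,
                           plc.pendant_length),
            leaf_bases,
        )
        assert impl_ll >= best[0] - 1e-6
        # and the engine's relative score matches absolute likelihoods
        ref_ll = _oracle_loglik(tree.tree.copy(),
                                {k_: v for k_, v in leaf_bases.items()
                                 if k_ != "QUERY"})
        assert impl_ll - ref_ll == pytest.approx(
            plc.score * len(cols), abs=1e-6
        )

    def test_pendant_positive_and_distal_bounded(self, small_reference):
        tree, aln, _, config = small_reference
        engine = PlacementEngine(tree, aln)
        lo, hi = config.window
        frags = extract_fragments(aln, lo, hi, config.target_len)
        placements, rejected = engine.place_all(frags)
        assert not rejected
        for plc in placements:
            assert plc.pendant_length > 0
            edge_len = tree.edge_node(plc.edge_id).length
            assert 0 <= plc.distal_length <= edge_len


class TestGraft:
    def test_no_placements_identity(self, small_tree):
        out = graft_placements(small_tree, [])
        assert out.tip_set == small_tree.tip_set
        assert out.total_branch_length() == pytest.approx(6.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_grafting_conserves_patristic_distances(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(int(rng.integers(5, 12)), rng)
        placements = []
        for i in range(4):
            edge = int(rng.integers(tree.n_edges))
            node = tree.edge_node(edge)
            placements.append(
                Placement(f"q{i}", edge,
                          distal_length=float(rng.uniform(0, node.length)),
                          pendant_length=float(rng.uniform(0.01, 0.2)),
                          score=0.0)
            )
        extended = graft_placements(tree, placements)
        assert extended.n_tips == tree.n_tips + 4
        for a in tree.tip_names:
            for b in tree.tip_names:
                if a < b:
                    assert oracle_path_length(extended, a, b) == pytest.approx(
                        oracle_path_length(tree, a, b), abs=1e-9
                    )

    def test_two_placements_one_edge_hand_path(self, small_tree):
        edge_b = small_tree.find_tip("B").edge_num
        p1 = Placement("f1", edge_b, 0.1, 0.05, 0.0)
        p2 = Placement("f2", edge_b, 0.3, 0.07, 0.0)
        extended = graft_placements(small_tree, [p2, p1])  # order-insensitive
        assert oracle_path_length(extended, "f1", "f2") == pytest.approx(
            (0.3 - 0.1) + 0.05 + 0.07
        )
        assert oracle_path_length(extended, "f1", "B") == pytest.approx(0.1 + 0.05)

    def test_distal_beyond_edge_rejected(self, small_tree):
        edge_b = small_tree.find_tip("B").edge_num
        bad = Placement("f1", edge_b, 5.0, 0.05, 0.0)
        with pytest.raises(EdgeReferenceError):
            graft_placements(small_tree, [bad])

    def test_fragment_name_collision_rejected(self, small_tree):
        edge_b = small_tree.find_tip("B").edge_num
        bad = Placement("A", edge_b, 0.1, 0.05, 0.0)
        with pytest.raises(IdentifierError):
            graft_placements(small_tree, [bad])


class TestStrip:
    def test_hand_path_preserved(self, small_tree):
        out = strip_tips(small_tree, {"A", "C"})
        assert out.tip_set == {"A", "C"}
        assert oracle_path_length(out, "A", "C") == pytest.approx(4.5)

    def test_keep_all_preserves_distances(self, small_tree):
        out = strip_tips(small_tree, small_tree.tip_set)
        for a in "ABC":
            for b in "ABC":
                if a < b:
                    assert oracle_path_length(out, a, b) == pytest.approx(
                        oracle_path_length(small_tree, a, b)
                    )

    def test_single_tip_rejected(self, small_tree):
        with pytest.raises(IdentifierError):
            strip_tips(small_tree, {"A"})
        with pytest.raises(IdentifierError):
            strip_tips(small_tree, {"A", "Z"})
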