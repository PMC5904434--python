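import itertools

import numpy as np
import pytest

from placefrag.errors import (
    IdentifierError,
    InsufficientOverlapError,
    PlacefragError,
    UndefinedCorrelationError,
)
from placefrag.metrics import (
    insertion_error,
    patristic_distances,
    rank_diversity,
    robinson_foulds,
    tip_to_tip_correlation,
)
from placefrag.model_io import Placement, ReferenceTree, Taxonomy
from placefrag.placement import graft_placements

from conftest import (
    all_five_tip_topologies,
    oracle_path_length,
    oracle_rf,
    random_tree,
)


class TestPatristic:
    def test_hand_example(self, small_tree):
        dm = patristic_distances(small_tree)
        d = {frozenset(p): dm[p[0], p[1]] for p in itertools.combinations("ABC", 2)}
        assert d[frozenset("AB")] == pytest.approx(3.0)
        assert d[frozenset("AC")] == pytest.approx(4.5)
        assert d[frozenset("BC")] == pytest.approx(5.5)
        assert np.allclose(np.diag(dm.data), 0.0)
        assert np.allclose(dm.data, dm.data.T)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_parent_walk_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(int(rng.integers(4, 9)), rng)
        dm = patristic_distances(tree)
        for a, b in itertools.combinations(sorted(tree.tip_set), 2):
            assert dm[a, b] == pytest.approx(
                oracle_path_length(tree, a, b), abs=1e-9
            )

    def test_unknown_tip_rejected(self, small_tree):
        with pytest.raises(IdentifierError):
            patristic_distances(small_tree, {"A", "Z"})


class TestInsertionError:
    def _extended(self, small_tree, distal=0.4, pendant=0.02):
        edge_a = small_tree.find_tip("A").edge_num
        plc = Placement("frag", edge_a, distal, pendant, 0.0)
        return graft_placements(small_tree, [plc])

    def test_attached_at_true_tip_is_zero(self, small_tree):
        ext = self._extended(small_tree, distal=0.0)
        assert insertion_error(ext, "frag", {"A"}, "lca") == pytest.approx(0.0)
        assert insertion_error(ext, "frag", {"A"}, "min") == pytest.approx(0.0)

    def test_ambiguous_hand_example(self, small_tree):
        # origins {A,B}; attachment on A's edge 0.4 above A: the LCA of A and
        # B is 0.6 further up, the nearest origin (A) is 0.4 down
        ext = self._extended(small_tree, distal=0.4)
        assert insertion_error(ext, "frag", {"A", "B"}, "lca") == pytest.approx(0.6)
        assert insertion_error(ext, "frag", {"A", "B"}, "min") == pytest.approx(0.4)

    def test_attachment_at_lca_node_is_zero(self, small_tree):
        ext = self._extended(small_tree, distal=1.0)  # exactly at LCA(A,B)
        assert insertion_error(ext, "frag", {"A", "B"}, "lca") == pytest.approx(0.0)

    def test_pendant_excluded_from_error(self, small_tree):
        short = self._extended(small_tree, distal=0.4, pendant=0.001)
        long_ = self._extended(small_tree, distal=0.4, pendant=1.5)
        for variant in ("lca", "min"):
            assert insertion_error(short, "frag", {"A"}, variant) == pytest.approx(
                insertion_error(long_, "frag", {"A"}, variant)
            )

    @pytest.mark.parametrize("seed", range(10))
    def test_min_lca_relationship_on_random_attachments(self, seed):
        # inside the clade spanned by the origins the min variant is the more
        # lenient one (min <= lca); outside, every path to an origin passes
        # through the LCA, so min exceeds lca by the LCA's distance to its
        # nearest origin exactly
        rng = np.random.default_rng(seed)
        tree = random_tree(int(rng.integers(5, 10)), rng)
        edge = int(rng.integers(tree.n_edges))
        node = tree.edge_node(edge)
        plc = Placement("frag", edge, float(rng.uniform(0, node.length)),
                        0.01, 0.0)
        ext = graft_placements(tree, [plc])
        tips = sorted(tree.tip_set)
        origins = set(rng.choice(tips, size=int(rng.integers(2, 4)),
                                 replace=False))
        err_min = insertion_error(ext, "frag", origins, "min")
        err_lca = insertion_error(ext, "frag", origins, "lca")
        origin_nodes = [ext.find_tip(o) for o in origins]
        lca = ext.tree.lca(origin_nodes)
        junction = ext.find_tip("frag").parent
        nearest = min(lca.distance(o) for o in origin_nodes)
        inside = junction in set(lca.traverse(include_self=True))
        if inside:
            # routing through the LCA is one candidate path, never forced
            assert err_min <= err_lca + nearest + 1e-12
        else:
            # outside the clade every path to an origin crosses the LCA
            assert err_min == pytest.approx(err_lca + nearest, abs=1e-9)

    def test_empty_origins_rejected(self, small_tree):
        ext = self._extended(small_tree)
        with pytest.raises(PlacefragError):
            insertion_error(ext, "frag", set(), "lca")


class TestTipToTipCorrelation:
    def test_self_and_scaled_copies(self, small_tree):
        assert tip_to_tip_correlation(small_tree, small_tree) == pytest.approx(1.0)
        doubled = small_tree.copy()
        for node in doubled.tree.postorder(include_self=False):
            node.length *= 2
        doubled = ReferenceTree(doubled.tree)
        assert tip_to_tip_correlation(small_tree, doubled) == pytest.approx(1.0)

    def test_disjoint_tip_sets_rejected(self, small_tree):
        other = ReferenceTree.from_newick("((X:1,Y:2):0.5,Z:3);")
        with pytest.raises(InsufficientOverlapError):
            tip_to_tip_correlation(small_tree, other)

    def test_zero_variance_rejected(self):
        star = ReferenceTree.from_newick("(A:1,B:1,C:1,D:1);")
        other = ReferenceTree.from_newick("((A:1,B:2):0.5,(C:3,D:1):0.2);")
        with pytest.raises(UndefinedCorrelationError):
            tip_to_tip_correlation(star, other)


class TestRobinsonFoulds:
    def test_lengths_do_not_matter(self):
        a = ReferenceTree.from_newick("((A:1,B:2):0.5,(C:3,D:4):0.1);")
        b = ReferenceTree.from_newick("((A:9,B:9):9,(C:9,D:9):9);")
        assert robinson_foulds(a, b) == 0

    def test_conflicting_quartets(self):
        a = ReferenceTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        b = ReferenceTree.from_newick("((A:1,C:1):1,(B:1,D:1):1);")
        assert robinson_foulds(a, b) == 2

    def test_resolved_vs_star(self):
        resolved = ReferenceTree.from_newick(
            "(((A:1,B:1):1,C:1):1,(D:1,E:1):1);"
        )
        star = ReferenceTree.from_newick("(A:1,B:1,C:1,D:1,E:1);")
        from conftest import oracle_splits

        n_internal = len(oracle_splits(resolved))
        assert n_internal == 2  # a 5-tip binary tree has n - 3 internal edges
        assert robinson_foulds(resolved, star) == n_internal

    def test_exhaustive_five_tip_topologies_vs_oracles(self):
        import dendropy

        trees = all_five_tip_topologies()
        taxa = dendropy.TaxonNamespace()
        dtrees = [
            dendropy.Tree.get(data=t.to_newick(), schema="newick",
                              taxon_namespace=taxa)
            for t in trees
        ]
        for d in dtrees:
            d.encode_bipartitions()
        for i, j in itertools.combinations(range(len(trees)), 2):
            got = robinson_foulds(trees[i], trees[j])
            assert got == robinson_foulds(trees[j], trees[i])
            assert got == oracle_rf(trees[i], trees[j])
            assert got == dendropy.calculate.treecompare.symmetric_difference(
                dtrees[i], dtrees[j]
            )
        for t in trees:
            assert robinson_foulds(t, t) == 0

    def test_tiny_overlap_warns_and_returns_zero(self, small_tree):
        other = ReferenceTree.from_newick("((A:1,B:1):1,X:1);")
        with pytest.warns(UserWarning):
            assert robinson_foulds(small_tree, other) == 0


class TestRankDiversity:
    def test_mean_of_within_clade_maxima(self):
        # genus g1 = {A,B} max distance 0.1; genus g2 = {C,D} max 0.3
        tree = ReferenceTree.from_newick(
            "((A:0.05,B:0.05):1,(C:0.15,D:0.15):1);"
        )
        tax = Taxonomy(
            lineages={t: ("p1", g) for t, g in
                      [("A", "g1"), ("B", "g1"), ("C", "g2"), ("D", "g2")]},
            ranks=("phylum", "genus"),
        )
        rd = rank_diversity(tree, tax)
        assert rd["genus"] == pytest.approx((0.1 + 0.3) / 2)
        # single phylum clade: the widest pair is A (or B) against C (or D),
        # 0.05 + 1 + 1 + 0.15
        assert rd["phylum"] == pytest.approx(2.2)

    def test_singleton_clades_omit_rank(self):
        tree = ReferenceTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        tax = Taxonomy(
            lineages={t: ("p1", f"g_{t}") for t in "ABCD"},
            ranks=("phylum", "genus"),
        )
        with pytest.warns(UserWarning, match="genus"):
            rd = rank_diversity(tree, tax)
        assert "genus" not in rd and "phylum" in rd
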