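import math

import pytest
from hypothesis import given, settings, strategies as st

import psmphylo as pp
from psmphylo.treekit import (
    CladeDefinition,
    binarize,
    collapse_to_families,
    extract_clade,
    lineages_at_time,
    read_newick,
    write_newick,
)


class TestReadNewick:
    def test_balanced_four_tip_parse(self):
        tree = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert tree.tip_labels == ["A", "B", "C", "D"]
        assert all(n.length == 1 for n in tree.preorder() if n.parent is not None)

    def test_polytomy_preserved_on_read(self):
        tree = read_newick("(A:1,B:1,C:1);")
        assert len(tree.root.children) == 3
        assert not tree.is_binary()

    def test_duplicate_tip_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate tip labels"):
            read_newick("((A,A),B);")

    def test_malformed_newick_reports_position(self):
        with pytest.raises(ValueError, match="malformed Newick"):
            read_newick("((A,B);")

    def test_quoted_labels_and_comments_stripped(self):
        tree = read_newick("('Fam one':1,[a comment]B:2);")
        assert tree.tip_labels == ["Fam one", "B"]

    def test_round_trip_preserves_topology_labels_lengths(self):
        text = "((A:1.5,B:2.25):0.5,(C:1,D:1):3);"
        tree = read_newick(text)
        again = read_newick(write_newick(tree))
        assert again.tip_labels == tree.tip_labels
        for a, b in zip(again.preorder(), tree.preorder()):
            assert a.label == b.label
            assert a.length == b.length


class TestCollapseToFamilies:
    def test_three_families_of_two_species(self):
        tree = read_newick("((s1:1,s2:1):1,((s3:1,s4:1):1,(s5:1,s6:1):1):1);")
        mapping = {"s1": "A", "s2": "A", "s3": "B", "s4": "B", "s5": "C", "s6": "C"}
        fam = collapse_to_families(tree, mapping)
        assert sorted(fam.tip_labels) == ["A", "B", "C"]
        assert fam.n_tips == 3

    def test_non_monophyletic_family_keeps_first_postorder_tip(self):
        # A's species (s1, s3) straddle B's: exemplar is the first postorder A tip
        tree = read_newick("((s1:1,s2:1):1,((s3:1,s4:1):1,s5:1):1);")
        mapping = {"s1": "A", "s3": "A", "s2": "B", "s4": "B", "s5": "C"}
        with pytest.warns(UserWarning, match="not monophyletic"):
            fam = collapse_to_families(tree, mapping)
        assert sorted(fam.tip_labels) == ["A", "B", "C"]
        # s1 is A's exemplar, s2 B's: (A,B) remain sisters, C outside
        mrca_ab = fam.mrca(["A", "B"])
        assert {t.label for t in fam.tips() if _under(t, mrca_ab)} == {"A", "B"}

    def test_unmapped_species_are_pruned(self):
        tree = read_newick("((s1:1,s2:1):1,s9:2);")
        fam = collapse_to_families(tree, {"s1": "A", "s2": "B"})
        assert sorted(fam.tip_labels) == ["A", "B"]

    def test_empty_intersection_is_error(self):
        tree = read_newick("(s1:1,s2:1);")
        with pytest.raises(ValueError, match="no mappable tips"):
            collapse_to_families(tree, {"x": "A"})


def _under(tip, ancestor):
    node = tip
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


class TestBinarize:
    def test_trichotomy_resolved_with_zero_length_edge(self):
        tree = binarize(read_newick("(A:1,B:1,C:1);"), seed=1)
        assert tree.is_binary()
        internals = [n for n in tree.preorder() if not n.is_tip]
        assert len(internals) == 2
        assert any(n.length == 0.0 for n in internals)

    def test_already_binary_tree_unchanged(self, balanced4):
        again = binarize(balanced4)
        assert write_newick(again) == write_newick(balanced4)

    def test_root_polytomy_of_five_adds_three_internals(self):
        tree = binarize(read_newick("(A:1,B:1,C:1,D:1,E:1);"))
        internals = [n for n in tree.preorder() if not n.is_tip]
        assert len(internals) == 4
        assert sum(1 for n in internals if n.length == 0.0) == 3

    def test_root_to_tip_paths_preserved(self):
        tree = read_newick("((A:1,B:2,C:3):1,(D:4,E:5,F:6,G:7):2);")
        def paths(t):
            out = {}
            for tip in t.tips():
                d, node = 0.0, tip
                while node.parent is not None:
                    d += node.length
                    node = node.parent
                out[tip.label] = d
            return out
        assert paths(binarize(tree)) == paths(tree)


class TestExtractClade:
    def test_members_give_induced_subtree_without_stem(self, balanced4):
        sub = extract_clade(balanced4, CladeDefinition("cherry", members=frozenset("AB")))
        assert sorted(sub.tip_labels) == ["A", "B"]
        assert sub.root.length is None

    def test_mrca_anchors_spanning_root_give_whole_tree(self, balanced4):
        sub = extract_clade(balanced4, CladeDefinition("all", mrca_anchors=("A", "D")))
        assert sorted(sub.tip_labels) == ["A", "B", "C", "D"]

    def test_missing_member_is_named_in_error(self, balanced4):
        with pytest.raises(KeyError, match="Z"):
            extract_clade(balanced4, CladeDefinition("bad", members=frozenset(["A", "Z"])))

    def test_commutes_with_collapse_on_monophyletic_families(self):
        sp = read_newick("((s1:1,s2:1):1,((s3:1,s4:1):1,(s5:1,s6:1):1):1);")
        mapping = {"s1": "A", "s2": "A", "s3": "B", "s4": "B", "s5": "C", "s6": "C"}
        collapsed_then_extracted = extract_clade(
            collapse_to_families(sp, mapping), CladeDefinition("bc", members=frozenset("BC"))
        )
        extracted_then_collapsed = collapse_to_families(
            extract_clade(sp, CladeDefinition("bc", members=frozenset(["s3", "s4", "s5", "s6"]))),
            mapping,
        )
        assert sorted(collapsed_then_extracted.tip_labels) == sorted(
            extracted_then_collapsed.tip_labels
        ) == ["B", "C"]


class TestLineagesAtTime:
    @pytest.fixture
    def depth10(self):
        return read_newick("((A:5,B:5):5,(C:5,D:5):5);")

    def test_zero_age_counts_tips(self, depth10):
        assert lineages_at_time(depth10, 0.0) == 4

    def test_beyond_root_age_counts_the_root_lineage(self, depth10):
        assert lineages_at_time(depth10, 12.0) == 1

    def test_between_root_and_nodes(self, depth10):
        assert lineages_at_time(depth10, 7.0) == 2

    def test_edge_above_node_counts_at_exact_node_age(self, depth10):
        assert lineages_at_time(depth10, 5.0) == 2

    def test_non_ultrametric_rejected_with_deviation(self):
        tree = read_newick("((A:5,B:3):5,(C:5,D:5):5);")
        with pytest.raises(ValueError, match="not ultrametric"):
            lineages_at_time(tree, 1.0)

    def test_non_increasing_step_function_on_yule_tree(self, yule200):
        root_age = yule200.ages()[id(yule200.root)]
        counts = [lineages_at_time(yule200, t) for t in
                  [root_age * i / 20 for i in range(21)]]
        assert counts[0] == 200
        assert counts[-1] == 1
        assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_default_clade_roster_ships_18_names():
    from psmphylo.treekit import default_clade_names

    names = default_clade_names()
    assert len(names) == 18
    assert "eudicots" in names and "rosids" in names


@settings(deadline=None, max_examples=25, derandomize=True)
@given(n=st.integers(3, 30), seed=st.integers(0, 10_000))
def test_binarize_preserves_tip_set_of_random_polytomous_trees(n, seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    # random polytomous tree: repeatedly merge 2-4 subtrees
    from psmphylo.treekit import Node, Phylogeny

    nodes = [Node(label=f"T{i}", length=1.0) for i in range(n)]
    while len(nodes) > 1:
        take = min(len(nodes), int(rng.integers(2, 5)))
        merged = Node(length=1.0)
        for _ in range(take):
            merged.add_child(nodes.pop(int(rng.integers(len(nodes)))))
        nodes.append(merged)
    tree = Phylogeny(nodes[0])
    resolved = binarize(tree)
    assert resolved.is_binary()
    assert sorted(resolved.tip_labels) == sorted(tree.tip_labels)
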