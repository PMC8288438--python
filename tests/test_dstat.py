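import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import psmphylo as pp
from helpers_oracle import all_binary_shapes, all_labelings, brute_force_d, shape_to_tree
from psmphylo.dstat import (
    ArrayTree,
    DResult,
    brownian_threshold_null,
    classify_regime,
    d_value,
    estimate_D,
    nodal_values,
    random_null,
    stable_seed,
)
from psmphylo.treekit import binarize, read_newick


class TestNodalValues:
    def test_clumped_hand_example(self, balanced4):
        vals = nodal_values(balanced4, dict(A=1, B=1, C=0, D=0))
        by_root = {n.parent is None: v for n, v in vals.items()}
        assert by_root[True] == 0.5
        internal = sorted(v for n, v in vals.items() if not n.is_tip and n.parent)
        assert internal == [0.0, 1.0]

    def test_constant_trait_gives_constant_nodes(self, balanced4):
        vals = nodal_values(balanced4, dict(A=0, B=0, C=0, D=0))
        assert all(v == 0 for v in vals.values())

    def test_dispersed_hand_example(self, balanced4):
        vals = nodal_values(balanced4, dict(A=1, B=0, C=1, D=0))
        assert all(v == 0.5 for n, v in vals.items() if not n.is_tip)

    def test_missing_tip_value_names_the_tip(self, balanced4):
        with pytest.raises(KeyError, match="D"):
            nodal_values(balanced4, dict(A=1, B=0, C=1))


class TestDValue:
    def test_clumped_and_dispersed_hand_values(self, balanced4):
        assert d_value(balanced4, dict(A=1, B=1, C=0, D=0)) == 1.0
        assert d_value(balanced4, dict(A=1, B=0, C=1, D=0)) == 2.0

    def test_constant_trait_has_zero_d(self, balanced4):
        assert d_value(balanced4, dict(A=1, B=1, C=1, D=1)) == 0.0

    def test_matches_bruteforce_on_all_small_shapes(self):
        # exhaustive oracle equivalence on every shape with <= 6 tips
        for n in range(2, 7):
            for skeleton in all_binary_shapes(n):
                tree = shape_to_tree(skeleton)
                at = ArrayTree(tree)
                for labeling in all_labelings(n):
                    assert d_value(at, labeling) == float(brute_force_d(tree, labeling))

    def test_invariant_to_child_swap_and_relabeling(self, balanced8):
        values = dict(zip("ABCDEFGH", [1, 0, 1, 1, 0, 0, 1, 0]))
        base = d_value(balanced8, values)
        swapped = read_newick(
            "(((H:1,G:1):1,(F:1,E:1):1):1,((D:1,C:1):1,(B:1,A:1):1):1);"
        )
        assert d_value(swapped, values) == base

    def test_moving_presence_out_of_clump_never_decreases_d(self, balanced8):
        # exhaustive monotonicity check on a balanced 8-tip tree
        tips = list("ABCDEFGH")
        for block in (2, 4):
            inside = tips[:block]
            values = {t: 1 if t in inside else 0 for t in tips}
            base = d_value(balanced8, values)
            for src in inside:
                for dst in tips[block:]:
                    moved = dict(values, **{src: 0, dst: 1})
                    assert d_value(balanced8, moved) >= base


class TestRandomNull:
    def test_mean_matches_exhaustive_enumeration(self, balanced4):
        # all C(4,2)=6 placements: d in {1,1,2,2,2,2}, mean 5/3
        ds = sorted(
            d_value(balanced4, {t: int(t in pair) for t in "ABCD"})
            for pair in itertools.combinations("ABCD", 2)
        )
        assert ds == [1, 1, 2, 2, 2, 2]
        null = random_null(balanced4, dict(A=1, B=1, C=0, D=0), B=2000, seed=11)
        se = null.d_values.std(ddof=1) / np.sqrt(null.B)
        assert abs(null.mean - 5 / 3) < 3 * se

    def test_single_replicate_is_reproducible(self, balanced4):
        values = dict(A=1, B=0, C=0, D=1)
        a = random_null(balanced4, values, B=1, seed=5)
        b = random_null(balanced4, values, B=1, seed=5)
        assert a.d_values[0] == b.d_values[0]

    def test_constant_trait_rejected(self, balanced4):
        with pytest.raises(ValueError, match="trait invariant"):
            random_null(balanced4, dict(A=1, B=1, C=1, D=1), B=10, seed=0)

    def test_prevalence_preserved_in_every_replicate(self, at200):
        values = {l: int(i < 30) for i, l in enumerate(at200.tip_labels)}
        rng = np.random.default_rng(0)
        base = at200.tip_vector(values)
        shuffled = rng.permuted(np.tile(base, (50, 1)), axis=1)
        assert (shuffled.sum(axis=1) == 30).all()


class TestBrownianThresholdNull:
    def test_star_like_tree_approaches_random_null(self):
        # tiny internal edges: threshold ranking approaches a uniform subset
        text = "((A:1,B:1):1e-9,(C:1,D:1):1e-9);"
        tree = read_newick(text)
        brown = brownian_threshold_null(tree, 2, B=2000, seed=2)
        rand = random_null(tree, dict(A=1, B=1, C=0, D=0), B=2000, seed=3)
        se = np.hypot(
            brown.d_values.std(ddof=1) / np.sqrt(brown.B),
            rand.d_values.std(ddof=1) / np.sqrt(rand.B),
        )
        assert abs(brown.mean - rand.mean) < 3 * se

    def test_two_deep_clades_give_clumped_d(self):
        # presences concentrate in one of two anciently separated clades
        text = "((A:1,B:1):100,(C:1,D:1):100);"
        tree = read_newick(text)
        brown = brownian_threshold_null(tree, 2, B=2000, seed=4)
        # clumped d = 1.0 on this tree; random mean is 5/3
        assert brown.mean < 1.2

    def test_reproducible_for_fixed_seed(self, balanced4):
        a = brownian_threshold_null(balanced4, 2, B=1, seed=9)
        b = brownian_threshold_null(balanced4, 2, B=1, seed=9)
        assert a.d_values[0] == b.d_values[0]

    def test_all_zero_lengths_rejected(self):
        tree = read_newick("((A:0,B:0):0,(C:0,D:0):0);")
        with pytest.raises(ValueError, match="no Brownian variance"):
            brownian_threshold_null(tree, 2, B=5, seed=0)

    def test_location_and_scale_of_brownian_are_irrelevant(self, at200):
        # thresholding by rank ignores the root value and sigma: scaling all
        # branch lengths by a constant leaves the null distribution identical
        scaled = pp.read_newick(at200_newick_scaled(at200, 7.3))
        a = brownian_threshold_null(at200, 40, B=200, seed=13)
        b = brownian_threshold_null(scaled, 40, B=200, seed=13)
        np.testing.assert_array_equal(a.d_values, b.d_values)


def at200_newick_scaled(at200, factor):
    from psmphylo.treekit import Phylogeny, write_newick

    tree = Phylogeny(at200.nodes[-1], validate=False).copy()
    for node in tree.preorder():
        if node.length is not None:
            node.length *= factor
    return write_newick(tree)


class TestEstimateD:
    def test_low_power_warning_below_25_tips(self, balanced8):
        values = dict(zip("ABCDEFGH", [1, 1, 1, 0, 0, 0, 1, 0]))
        with pytest.warns(UserWarning, match="low power"):
            estimate_D(balanced8, values, B=50, seed=1)

    def test_reproducible_given_seed(self, at200):
        values = {l: int(i < 60) for i, l in enumerate(at200.tip_labels)}
        a = estimate_D(at200, values, B=100, seed=42)
        b = estimate_D(at200, values, B=100, seed=42)
        assert a.D == b.D and a.p_random == b.p_random and a.p_brownian == b.p_brownian

    def test_D_identity_links_components(self, at200):
        values = {l: int(i % 3 == 0) for i, l in enumerate(at200.tip_labels)}
        r = estimate_D(at200, values, B=200, seed=7)
        expected = (r.d_obs - r.mean_d_brownian) / (r.mean_d_random - r.mean_d_brownian)
        assert r.D == pytest.approx(expected, abs=1e-12)
        assert 0 <= r.p_random <= 1 and 0 <= r.p_brownian <= 1

    def test_plus_one_correction_flag(self, at200):
        values = {l: int(i < 60) for i, l in enumerate(at200.tip_labels)}
        r = estimate_D(at200, values, B=100, seed=42, plus_one=True)
        assert r.p_random >= 1 / 101 and r.p_brownian >= 1 / 101

    def test_degenerate_prevalence_rejected(self, at200):
        values = {l: 1 for l in at200.tip_labels}
        with pytest.raises(ValueError, match="trait invariant"):
            estimate_D(at200, values, B=10, seed=0)


class TestClassifyRegime:
    def _result(self, D, p_random):
        return DResult(
            d_obs=0, mean_d_random=1, mean_d_brownian=0, D=D,
            p_random=p_random, p_brownian=0.5, n_tips=300, prevalence_k=100,
            B=1000, seed=0, classification="", significant=p_random < 0.05,
        )

    def test_weak_clustering_significant(self):
        # e.g. alkaloids across seed plants: D=0.785424, shuffle p=0.016
        assert classify_regime(self._result(0.785424, 0.016)) == "W"

    def test_weak_clustering_not_significant(self):
        # e.g. steroids: D=0.975770, shuffle p=0.400 - still weak clustering
        r = self._result(0.975770, 0.400)
        assert classify_regime(r) == "W"
        assert not r.significant

    def test_sign_rules(self):
        assert classify_regime(self._result(-0.5, 0.001)) == "S"
        assert classify_regime(self._result(0.0, 0.2)) == "B0"
        assert classify_regime(self._result(1.2, 0.5)) == "R"

    def test_overdispersion_needs_extreme_upper_tail(self):
        assert classify_regime(self._result(1.4, 0.999)) == "OD"
        assert classify_regime(self._result(1.4, 0.90)) == "R"


def test_stable_seed_is_deterministic_and_bounded():
    a = stable_seed(3, "rosids", "alkaloids")
    assert a == stable_seed(3, "rosids", "alkaloids")
    assert a != stable_seed(3, "rosids", "quinones")
    assert 0 <= a < 2**31


@settings(deadline=None, max_examples=20, derandomize=True)
@given(seed=st.integers(0, 10**6), k=st.integers(1, 7))
def test_d_invariant_to_tip_input_order(seed, k):
    tree = pp.simulate_yule_tree(8, seed=seed % 1000)
    labels = tree.tip_labels
    values = {l: int(i < k) for i, l in enumerate(labels)}
    shuffled_items = sorted(values.items(), reverse=bool(seed % 2))
    assert d_value(tree, dict(shuffled_items)) == d_value(tree, values)
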