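"""The D statistic for binary traits on rooted trees.

For a binary trait on a fully dichotomous tree, each internal node is
assigned the unweighted mean of its two children's values (tips carry their
observed 0/1), and d is the sum over all edges of the absolute difference
between parent and child values.  d is small when presences clump in few
clades and large when they are scattered.

D locates the observed d between the means of two null distributions
computed with the identical d operator:

    D = (d_obs - mean d_Brownian) / (mean d_random - mean d_Brownian)

* the *tip-shuffling* null permutes the observed values over tips,
  preserving prevalence exactly (D = 1 when the trait looks shuffled);
* the *threshold-Brownian* null simulates a continuous character with
  independent normal increments of variance equal to branch length, then
  marks the k highest-ranked tips present (D = 0 when the trait looks like
  a thresholded Brownian character).

Because the observed value and both nulls share one d operator, D is
self-calibrating: its expectation under each generating regime does not
depend on the nodal-estimation convention.  Branch lengths enter only the
Brownian simulation; d itself and the permutation null are purely
topological.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .treekit import Node, Phylogeny, binarize

__all__ = [
    "NullDistribution",
    "DResult",
    "ArrayTree",
    "nodal_values",
    "d_value",
    "random_null",
    "brownian_threshold_null",
    "estimate_D",
    "classify_regime",
    "stable_seed",
]

LOW_POWER_TIPS = 25  # below this the statistic has little power
_DEGENERATE_TOL = 1e-9


def stable_seed(*parts) -> int:
    """Deterministic sub-2^31 seed from arbitrary hashable parts.

    Used to derive per-cell and per-replicate seeds from a master seed so
    results do not depend on execution order.
    """
    text = "\x1f".join(repr(p) for p in parts)
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Array encoding of a binarized tree
# ---------------------------------------------------------------------------


class ArrayTree:
    """Postorder array encoding of a fully dichotomous rooted tree.

    Node indices are postorder positions (children before parents, root
    last), which lets the nodal-mean recursion and the Brownian recursion
    run as short vectorized loops over many replicates at once.
    """

    def __init__(self, tree: Phylogeny):
        if not tree.is_binary():
            raise ValueError("tree must be fully dichotomous (run binarize first)")
        self.nodes: list[Node] = list(tree.postorder())
        index = {id(n): i for i, n in enumerate(self.nodes)}
        n = len(self.nodes)
        self.n_nodes = n
        self.parent = np.full(n, -1, dtype=np.int64)
        self.left = np.full(n, -1, dtype=np.int64)
        self.right = np.full(n, -1, dtype=np.int64)
        lengths = np.full(n, np.nan)
        is_tip = np.zeros(n, dtype=bool)
        for i, node in enumerate(self.nodes):
            if node.parent is not None:
                self.parent[i] = index[id(node.parent)]
            if node.is_tip:
                is_tip[i] = True
            else:
                self.left[i] = index[id(node.children[0])]
                self.right[i] = index[id(node.children[1])]
            if node.length is not None:
                lengths[i] = node.length
        self.is_tip = is_tip
        self.tip_index = np.flatnonzero(is_tip)
        self.internal_index = np.flatnonzero(~is_tip)  # postorder, root last
        self.tip_labels = [self.nodes[i].label for i in self.tip_index]
        self.n_tips = len(self.tip_index)
        self.raw_lengths = lengths

    def tip_vector(self, tip_values: Mapping[str, int]) -> np.ndarray:
        missing = [l for l in self.tip_labels if l not in tip_values]
        if missing:
            raise KeyError(f"missing tip values for: {missing}")
        return np.array([tip_values[l] for l in self.tip_labels], dtype=float)

    def brownian_lengths(self) -> np.ndarray:
        """Edge lengths for the Brownian simulation; missing -> 1 (warned)."""
        lengths = self.raw_lengths.copy()
        n_missing = int(np.isnan(lengths[self.parent >= 0]).sum())
        if n_missing:
            warnings.warn(
                f"{n_missing} branch lengths missing; using unit lengths for "
                "the Brownian simulation",
                stacklevel=3,
            )
            lengths = np.where(np.isnan(lengths), 1.0, lengths)
        lengths[np.isnan(lengths)] = 0.0  # root edge
        if lengths[self.parent >= 0].sum() <= 0:
            raise ValueError("no Brownian variance: all branch lengths are zero")
        return lengths

    # -- vectorized kernels ------------------------------------------------

    def d_many(self, tip_matrix: np.ndarray) -> np.ndarray:
        """d for each row of a (B, n_tips) matrix of tip values."""
        tip_matrix = np.atleast_2d(np.asarray(tip_matrix, dtype=float))
        B = tip_matrix.shape[0]
        vals = np.empty((B, self.n_nodes))
        vals[:, self.tip_index] = tip_matrix
        for i in self.internal_index:
            vals[:, i] = 0.5 * (vals[:, self.left[i]] + vals[:, self.right[i]])
        nonroot = np.flatnonzero(self.parent >= 0)
        return np.abs(vals[:, nonroot] - vals[:, self.parent[nonroot]]).sum(axis=1)

    def nodal_values_one(self, tip_vector: np.ndarray) -> np.ndarray:
        vals = np.empty(self.n_nodes)
        vals[self.tip_index] = tip_vector
        for i in self.internal_index:
            vals[i] = 0.5 * (vals[self.left[i]] + vals[self.right[i]])
        return vals

    def simulate_threshold_tips(
        self, k: int, B: int, rng: np.random.Generator
    ) -> np.ndarray:
        """Threshold-Brownian binary tips: (B, n_tips) with exactly k ones.

        A continuous character starts at 0 at the root and accumulates
        independent normal increments of variance = branch length down every
        edge; the k highest-valued tips are marked present.  Rank ties
        (possible across zero-length edges) are broken by a seeded random
        key.  The root value and the overall variance scale are irrelevant
        by rank invariance.
        """
        if not 0 < k < self.n_tips:
            raise ValueError(f"degenerate prevalence k={k} for {self.n_tips} tips")
        lengths = self.brownian_lengths()
        x = np.empty((B, self.n_nodes))
        root = self.n_nodes - 1
        x[:, root] = 0.0
        # preorder = reversed postorder
        for i in range(self.n_nodes - 2, -1, -1):
            scale = np.sqrt(lengths[i])
            x[:, i] = x[:, self.parent[i]] + (
                rng.standard_normal(B) * scale if scale > 0 else 0.0
            )
        tips = x[:, self.tip_index]
        tie_break = rng.random(tips.shape)
        # top-k per row, descending by value then by the random key
        order = np.lexsort((tie_break, -tips), axis=-1)
        out = np.zeros((B, self.n_tips), dtype=np.int8)
        rows = np.arange(B)[:, None]
        out[rows, order[:, :k]] = 1
        return out


def _as_array_tree(tree: Phylogeny | ArrayTree) -> ArrayTree:
    if isinstance(tree, ArrayTree):
        return tree
    if not tree.is_binary():
        tree = binarize(tree)
    return ArrayTree(tree)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class NullDistribution:
    """Replicated d values under one null model."""

    kind: str  # "random_shuffle" | "brownian_threshold"
    d_values: np.ndarray
    B: int
    seed: int | None

    def __post_init__(self):
        self.d_values = np.asarray(self.d_values, dtype=float)
        if self.B < 1 or len(self.d_values) != self.B:
            raise ValueError("need B >= 1 replicates with matching d_values")
        if (self.d_values < 0).any():
            raise ValueError("d values must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.d_values.mean())


@dataclass
class DResult:
    """One D-statistic estimate for a binary trait on a tree."""

    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float
    p_random: float
    p_brownian: float
    n_tips: int
    prevalence_k: int
    B: int
    seed: int | None
    classification: str
    significant: bool

    def to_dict(self) -> dict:
        return {
            "d_obs": self.d_obs,
            "mean_d_random": self.mean_d_random,
            "mean_d_brownian": self.mean_d_brownian,
            "D": self.D,
            "p_random": self.p_random,
            "p_brownian": self.p_brownian,
            "n_tips": self.n_tips,
            "prevalence_k": self.prevalence_k,
            "B": self.B,
            "seed": self.seed,
            "classification": self.classification,
            "significant": self.significant,
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def nodal_values(
    tree: Phylogeny | ArrayTree, tip_values: Mapping[str, int]
) -> dict[Node, float]:
    """Estimated node values: tips as observed, internals the unweighted
    mean of their two children (branch lengths play no role)."""
    at = _as_array_tree(tree)
    vals = at.nodal_values_one(at.tip_vector(tip_values))
    return {at.nodes[i]: float(vals[i]) for i in range(at.n_nodes)}


def d_value(tree: Phylogeny | ArrayTree, tip_values: Mapping[str, int]) -> float:
    """Sum of |parent - child| over all edges: the raw clumping measure d."""
    at = _as_array_tree(tree)
    return float(at.d_many(at.tip_vector(tip_values)[None, :])[0])


def random_null(
    tree: Phylogeny | ArrayTree,
    tip_values: Mapping[str, int],
    B: int = 1000,
    seed: int | None = None,
) -> NullDistribution:
    """Tip-shuffling null: permute observed values over tips B times."""
    at = _as_array_tree(tree)
    base = at.tip_vector(tip_values)
    k = int(base.sum())
    if not 0 < k < at.n_tips:
        raise ValueError("trait invariant: all tips share one state")
    rng = np.random.default_rng(seed)
    shuffled = rng.permuted(np.tile(base, (B, 1)), axis=1)
    return NullDistribution("random_shuffle", at.d_many(shuffled), B, seed)


def brownian_threshold_null(
    tree: Phylogeny | ArrayTree,
    prevalence_k: int,
    B: int = 1000,
    seed: int | None = None,
) -> NullDistribution:
    """Threshold-Brownian null at the observed prevalence."""
    at = _as_array_tree(tree)
    rng = np.random.default_rng(seed)
    tips = at.simulate_threshold_tips(prevalence_k, B, rng)
    return NullDistribution("brownian_threshold", at.d_many(tips), B, seed)


def estimate_D(
    tree: Phylogeny | ArrayTree,
    tip_values: Mapping[str, int],
    B: int = 1000,
    seed: int | None = None,
    *,
    alpha: float = 0.05,
    plus_one: bool = False,
) -> DResult:
    """Estimate D with both nulls and classify the signal regime.

    p_random is the fraction of shuffling replicates with d <= d_obs (small
    when the trait is more clumped than random); p_brownian is the fraction
    of Brownian replicates with d >= d_obs (small when the trait is more
    dispersed than a thresholded Brownian character).  With ``plus_one``
    both proportions use the (r+1)/(B+1) correction.
    """
    at = _as_array_tree(tree)
    base = at.tip_vector(tip_values)
    n = at.n_tips
    k = int(base.sum())
    if n < 4:
        raise ValueError("need at least 4 tips")
    if not 0 < k < n:
        raise ValueError("trait invariant: all tips share one state")
    if n < LOW_POWER_TIPS:
        warnings.warn(
            f"low power: the D statistic has little power for trees with "
            f"fewer than {LOW_POWER_TIPS} tips (n={n})",
            stacklevel=2,
        )

    d_obs = float(at.d_many(base[None, :])[0])
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    seed_rand, seed_brown = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)]
    rand = random_null(at, tip_values, B=B, seed=seed_rand)
    brown = brownian_threshold_null(at, k, B=B, seed=seed_brown)

    denom = rand.mean - brown.mean
    if abs(denom) < _DEGENERATE_TOL:
        raise ValueError(
            "degenerate normalization: the two null means coincide "
            f"(|mean_random - mean_brownian| = {abs(denom):.3g})"
        )
    D = (d_obs - brown.mean) / denom

    if plus_one:
        p_random = (float((rand.d_values <= d_obs).sum()) + 1) / (B + 1)
        p_brownian = (float((brown.d_values >= d_obs).sum()) + 1) / (B + 1)
    else:
        p_random = float((rand.d_values <= d_obs).sum()) / B
        p_brownian = float((brown.d_values >= d_obs).sum()) / B

    label = _regime_label(D, p_random, alpha)
    return DResult(
        d_obs=d_obs,
        mean_d_random=rand.mean,
        mean_d_brownian=brown.mean,
        D=float(D),
        p_random=p_random,
        p_brownian=p_brownian,
        n_tips=n,
        prevalence_k=k,
        B=B,
        seed=seed,
        classification=label,
        significant=bool(p_random < alpha),
    )


def _regime_label(D: float, p_random: float, alpha: float) -> str:
    if D < 0:
        return "S"
    if D == 0:
        return "B0"
    if D < 1:
        return "W"
    # D >= 1: random, or overdispersed when the upper tail is extreme
    if D > 1 and p_random > 1 - alpha:
        return "OD"
    return "R"


def classify_regime(result: DResult, alpha: float = 0.05) -> str:
    """Signal regime from D (and the shuffle p-value for overdispersion).

    S strong clustering (D < 0); B0 exactly Brownian-like (D = 0); W weak
    clustering (0 < D < 1); R random-like (D >= 1); OD overdispersed
    (D > 1 with the shuffle null's upper tail below alpha).
    """
    return _regime_label(result.D, result.p_random, alpha)
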