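"""Synthetic family trees and trait matrices with known signal regimes.

Every pipeline stage can be exercised without any external data: a Yule
(pure-birth) tree stands in for the published family-level phylogeny, and
binary trait columns are generated under four regimes spanning the D scale —
threshold-Brownian (D ~ 0), uniform-random (D ~ 1), single-clade clumped
(D < 0) and maximally overdispersed (D > 1).  The threshold-Brownian
generator is the very same code path the estimator's null uses, which is
what makes the self-calibration tests meaningful.

The ``paperlike`` preset mirrors the shape of the study dataset this package
was built around: 437 seed-plant families by 8 metabolite classes, with
per-class presence counts fixed at 245, 221, 206, 175, 167, 162, 153 and 82
families (flavonoids down to quinones).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import traitkit
from .dstat import ArrayTree, stable_seed
from .traitkit import ABSENT, PRESENT, TraitMatrix, write_matrix_tsv
from .treekit import Node, Phylogeny, binarize, write_newick

__all__ = [
    "RegimeSpec",
    "SyntheticStudy",
    "REGIMES",
    "PAPERLIKE_CLASS_COUNTS",
    "PAPERLIKE_N_FAMILIES",
    "simulate_yule_tree",
    "simulate_trait",
    "make_synthetic_study",
    "paperlike_study",
]

REGIMES = ("brownian_threshold", "random", "clumped", "overdispersed")

#: Presence counts (families out of 437) used by the ``paperlike`` preset.
PAPERLIKE_CLASS_COUNTS: dict[str, int] = {
    "flavonoids": 245,
    "alkaloids": 221,
    "terpenoids": 206,
    "tannins": 175,
    "phenolic_acids": 167,
    "phenylpropanoids": 162,
    "steroids": 153,
    "quinones": 82,
}
PAPERLIKE_N_FAMILIES = 437


@dataclass(frozen=True)
class RegimeSpec:
    """A trait-generating regime at a fixed prevalence."""

    regime: str
    prevalence: float
    seed: int | None = None

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be strictly between 0 and 1")


@dataclass
class SyntheticStudy:
    """A generated (tree, matrix, truth) bundle for testing and calibration."""

    tree: Phylogeny
    matrix: TraitMatrix
    truth: dict[str, RegimeSpec]

    def __post_init__(self):
        if set(self.matrix.families) != set(self.tree.tip_labels):
            raise ValueError("matrix families must equal tree tips")
        if set(self.truth) != set(self.matrix.classes):
            raise ValueError("every class needs a truth entry")

    def write(self, out_dir: str | os.PathLike) -> None:
        """Materialize tree (Newick), matrix (TSV) and truth (JSON)."""
        os.makedirs(out_dir, exist_ok=True)
        write_newick(self.tree, os.path.join(out_dir, "tree.nwk"))
        write_matrix_tsv(self.matrix, os.path.join(out_dir, "matrix.tsv"))
        truth = {
            name: {"regime": s.regime, "prevalence": s.prevalence, "seed": s.seed}
            for name, s in self.truth.items()
        }
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int | None = None
) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` tips.

    Lineages split at rate ``birth_rate`` each; the tree starts from a root
    bifurcation at time 0, and after the last split runs one further
    exponential waiting time so pendant edges have positive length.  The
    result is ultrametric with tip labels F0001..F{n}, assigned in tip
    order.  Expected root-to-tip depth grows like ln(n)/birth_rate.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)
    root = Node()
    t = 0.0
    active: list[tuple[Node, float]] = []  # (pendant node, birth time)
    for _ in range(2):
        active.append((root.add_child(Node()), 0.0))
    while len(active) < n_tips:
        n = len(active)
        t += rng.exponential(1.0 / (birth_rate * n))
        idx = int(rng.integers(n))
        node, born = active.pop(idx)
        node.length = t - born
        for _ in range(2):
            active.append((node.add_child(Node()), t))
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for node, born in active:
        node.length = t - born
    tree = Phylogeny(root, validate=False)
    width = max(4, len(str(n_tips)))
    for i, tip in enumerate(tree.tips(), start=1):
        tip.label = f"F{i:0{width}d}"
    tree._validate()
    return tree


# ---------------------------------------------------------------------------
# Trait generation
# ---------------------------------------------------------------------------


def simulate_trait(
    tree: Phylogeny | ArrayTree, spec: RegimeSpec
) -> dict[str, int]:
    """Generate one binary trait under a regime; exactly k tips are present.

    k = round(prevalence * n_tips), half up.  The threshold-Brownian regime
    delegates to the estimator's own null simulator (one shared code path);
    the other regimes are defined topologically, so branch lengths never
    influence them.
    """
    at = tree if isinstance(tree, ArrayTree) else ArrayTree(binarize(tree))
    n = at.n_tips
    k = _round_half_up(spec.prevalence * n)
    if not 0 < k < n:
        raise ValueError(f"degenerate prevalence: k={k} of {n} tips")
    rng = np.random.default_rng(spec.seed)

    if spec.regime == "brownian_threshold":
        row = at.simulate_threshold_tips(k, 1, rng)[0]
        values = row.astype(int)
    elif spec.regime == "random":
        values = np.zeros(n, dtype=int)
        values[rng.permutation(n)[:k]] = 1
    elif spec.regime == "clumped":
        values = _clumped_assignment(at, k)
    else:  # overdispersed
        values = _overdispersed_assignment(at, k)
    assert int(values.sum()) == k
    return {label: int(v) for label, v in zip(at.tip_labels, values)}


def _tips_below(at: ArrayTree) -> list[list[int]]:
    """Tip positions (in at.tip order) below each node, postorder-built."""
    tip_pos = {int(node_i): p for p, node_i in enumerate(at.tip_index)}
    below: list[list[int]] = [[] for _ in range(at.n_nodes)]
    for i in range(at.n_nodes):
        if at.is_tip[i]:
            below[i] = [tip_pos[i]]
        else:
            below[i] = below[at.left[i]] + below[at.right[i]]
    return below


def _edge_depths(at: ArrayTree) -> np.ndarray:
    """Edge-count depth of each node from the root (topological)."""
    depth = np.zeros(at.n_nodes, dtype=int)
    for i in range(at.n_nodes - 2, -1, -1):  # preorder, skipping root
        depth[i] = depth[at.parent[i]] + 1
    return depth


def _clumped_assignment(at: ArrayTree, k: int) -> np.ndarray:
    """Fill the clade of size nearest k; trim or top up deterministically.

    Trimming keeps the clade's first k tips in tip order; topping up adds
    outside tips nearest the clade root by edge-count path distance, ties
    broken by tip label.
    """
    below = _tips_below(at)
    # candidate clades: every node's tip set (tips themselves are size-1)
    sizes = np.array([len(b) for b in below])
    # prefer the closest size; among ties the smaller clade, then the
    # earliest postorder position — all deterministic
    best = min(range(at.n_nodes), key=lambda i: (abs(sizes[i] - k), sizes[i], i))
    chosen = list(below[best])
    values = np.zeros(at.n_tips, dtype=int)
    if len(chosen) >= k:
        for p in sorted(chosen)[:k]:
            values[p] = 1
        return values
    for p in chosen:
        values[p] = 1
    # top up with nearest outside tips by path distance to the clade root
    depth = _edge_depths(at)
    anc_of_best = set()
    j = best
    while j != -1:
        anc_of_best.add(j)
        j = int(at.parent[j])

    def path_dist(tip_node: int) -> int:
        # climb until we hit an ancestor of the chosen clade root
        steps = 0
        j = tip_node
        while j not in anc_of_best:
            j = int(at.parent[j])
            steps += 1
        return steps + (depth[best] - depth[j])

    outside = [
        (path_dist(int(at.tip_index[p])), at.tip_labels[p], p)
        for p in range(at.n_tips)
        if values[p] == 0
    ]
    outside.sort()
    for _, _, p in outside[: k - len(chosen)]:
        values[p] = 1
    return values


def _overdispersed_assignment(at: ArrayTree, k: int) -> np.ndarray:
    """Spread k presences as evenly as the topology allows.

    Recursive proportional allocation: at each internal node the quota is
    split between the two child subtrees in proportion to their tip counts
    (half-up, extra to the left child), clamped to feasibility.  At every
    split the two sides disagree as much as the quota permits, e.g. one
    presence per cherry on a balanced tree at half prevalence.
    """
    below = _tips_below(at)
    sizes = np.array([len(b) for b in below])
    values = np.zeros(at.n_tips, dtype=int)
    root = at.n_nodes - 1
    stack = [(root, k)]
    while stack:
        node, quota = stack.pop()
        if at.is_tip[node]:
            if quota:
                values[below[node][0]] = 1
            continue
        left, right = int(at.left[node]), int(at.right[node])
        n_l, n_r = int(sizes[left]), int(sizes[right])
        q_l = _round_half_up(quota * n_l / (n_l + n_r))
        q_l = max(quota - n_r, min(n_l, q_l))
        stack.append((left, q_l))
        stack.append((right, quota - q_l))
    return values


# ---------------------------------------------------------------------------
# Study assembly
# ---------------------------------------------------------------------------


def make_synthetic_study(
    n_families: int,
    classes_with_regimes: Mapping[str, RegimeSpec],
    birth_rate: float = 1.0,
    seed: int | None = None,
) -> SyntheticStudy:
    """One Yule tree plus one generated trait column per class.

    Class specs without an explicit seed get one derived deterministically
    from the master seed and the class name, so studies are reproducible
    and classes independent.
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    if not classes_with_regimes:
        raise ValueError("need at least one class")
    tree = simulate_yule_tree(n_families, birth_rate, seed=stable_seed(seed, "tree"))
    at = ArrayTree(binarize(tree))
    columns = {}
    truth = {}
    for name, spec in classes_with_regimes.items():
        if spec.seed is None:
            spec = RegimeSpec(spec.regime, spec.prevalence, stable_seed(seed, "trait", name))
        truth[name] = spec
        trait = simulate_trait(at, spec)
        columns[name] = [
            PRESENT if trait[f] else ABSENT for f in tree.tip_labels
        ]
    cells = pd.DataFrame(columns, index=tree.tip_labels, dtype=np.int8)
    return SyntheticStudy(tree=tree, matrix=TraitMatrix(cells), truth=truth)


def paperlike_study(seed: int | None = None, birth_rate: float = 1.0) -> SyntheticStudy:
    """The default preset: 437 families x 8 classes, threshold-Brownian
    columns whose presence counts reproduce the study's printed per-class
    family counts exactly."""
    specs = {
        name: RegimeSpec(
            "brownian_threshold", count / PAPERLIKE_N_FAMILIES, seed=None
        )
        for name, count in PAPERLIKE_CLASS_COUNTS.items()
    }
    return make_synthetic_study(PAPERLIKE_N_FAMILIES, specs, birth_rate, seed=seed)
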