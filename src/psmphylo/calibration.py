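"""Simulation experiments that calibrate the estimator against its own nulls.

The D statistic's defining property is self-calibration: when a trait is
generated by one of the null models, the estimate should land on that
null's anchor (0 for threshold-Brownian, 1 for uniform shuffling), and its
shuffle p-value should be uniform.  These experiments generate traits with
known regimes on Yule trees and measure where the estimates fall; the test
suite and the reproduction script both run them.

Default problem sizes (200-tip trees, 500 permutation replicates, 50-100
trait replicates) keep each experiment at desk scale — seconds to a couple
of minutes on one core — while leaving Monte-Carlo error well inside the
tolerances the checks use.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest

from .dstat import ArrayTree, estimate_D, stable_seed
from .screen import run_robustness
from .synthdata import RegimeSpec, make_synthetic_study, simulate_trait, simulate_yule_tree
from .traitkit import TraitMatrix
from .treekit import CladeDefinition, binarize

__all__ = [
    "self_calibration",
    "regime_ordering",
    "p_uniformity",
    "clumped_subsampling_stability",
]


def _study_tree(n_tips: int, seed, tag: str) -> ArrayTree:
    tree = simulate_yule_tree(n_tips, seed=stable_seed(seed, tag))
    return ArrayTree(binarize(tree))


def self_calibration(
    n_tips: int = 200,
    prevalence: float = 0.3,
    B: int = 500,
    n_replicates: int = 100,
    seed: int | None = None,
) -> dict:
    """Estimate D on traits with known generating regimes, one Yule tree.

    Returns per-regime D estimates plus their means and, for the clumped
    regime, the fraction of strictly negative estimates.
    """
    at = _study_tree(n_tips, seed, "selfcal-tree")
    out: dict[str, list[float]] = {"brownian_threshold": [], "random": [], "clumped": []}
    for regime in out:
        for i in range(n_replicates):
            spec = RegimeSpec(regime, prevalence, seed=stable_seed(seed, regime, i))
            trait = simulate_trait(at, spec)
            result = estimate_D(at, trait, B=B, seed=stable_seed(seed, "est", regime, i))
            out[regime].append(result.D)
    return {
        "D_values": out,
        "mean_D_brownian": float(np.mean(out["brownian_threshold"])),
        "mean_D_random": float(np.mean(out["random"])),
        "frac_negative_clumped": float(np.mean(np.array(out["clumped"]) < 0)),
        "n_replicates": n_replicates,
        "n_tips": n_tips,
        "B": B,
    }


def regime_ordering(
    n_studies: int = 50,
    n_tips: int = 200,
    prevalence: float = 0.3,
    B: int = 500,
    seed: int | None = None,
) -> dict:
    """Across independent synthetic studies, does the estimated D order the
    regimes clumped < brownian < random (and random <= overdispersed)?"""
    regimes = ("clumped", "brownian_threshold", "random", "overdispersed")
    per_regime: dict[str, list[float]] = {r: [] for r in regimes}
    core_ordered = 0
    full_ordered = 0
    for s in range(n_studies):
        specs = {r: RegimeSpec(r, prevalence) for r in regimes}
        study = make_synthetic_study(n_tips, specs, seed=stable_seed(seed, "study", s))
        at = ArrayTree(binarize(study.tree))
        D: dict[str, float] = {}
        for r in regimes:
            trait = study.matrix.column_values(r, study.tree.tip_labels)
            D[r] = estimate_D(at, trait, B=B, seed=stable_seed(seed, "est", s, r)).D
            per_regime[r].append(D[r])
        if D["clumped"] < D["brownian_threshold"] < D["random"]:
            core_ordered += 1
            if D["random"] <= D["overdispersed"]:
                full_ordered += 1
    return {
        "ordering_rate": core_ordered / n_studies,
        "full_ordering_rate": full_ordered / n_studies,
        "mean_D": {r: float(np.mean(v)) for r, v in per_regime.items()},
        "n_studies": n_studies,
    }


def p_uniformity(
    n_tips: int = 200,
    prevalence: float = 0.3,
    B: int = 200,
    n_replicates: int = 500,
    seed: int | None = None,
) -> dict:
    """When the trait is itself a uniform shuffle, the shuffle p-value
    should be (approximately) uniform; summarized by a KS test."""
    at = _study_tree(n_tips, seed, "punif-tree")
    ps = []
    for i in range(n_replicates):
        trait = simulate_trait(
            at, RegimeSpec("random", prevalence, seed=stable_seed(seed, "trait", i))
        )
        ps.append(estimate_D(at, trait, B=B, seed=stable_seed(seed, "est", i)).p_random)
    stat, pvalue = kstest(ps, "uniform")
    return {
        "p_values": ps,
        "ks_statistic": float(stat),
        "ks_pvalue": float(pvalue),
        "n_replicates": n_replicates,
        "B": B,
    }


def clumped_subsampling_stability(
    n_tips: int = 200,
    prevalence: float = 0.3,
    fraction: float = 0.95,
    reps: int = 20,
    B: int = 500,
    seed: int | None = None,
) -> dict:
    """Significance-flip rate when presences of a strongly clumped trait
    are randomly demoted to unknown (single whole-tree cell)."""
    tree = simulate_yule_tree(n_tips, seed=stable_seed(seed, "robust-tree"))
    trait = simulate_trait(tree, RegimeSpec("clumped", prevalence, seed=stable_seed(seed, "t")))
    import pandas as pd

    cells = pd.DataFrame(
        {"clumped_class": [trait[f] for f in tree.tip_labels]},
        index=tree.tip_labels,
        dtype=np.int8,
    )
    matrix = TraitMatrix(cells)
    clades = [CladeDefinition("all", members=frozenset(tree.tip_labels))]
    result = run_robustness(
        tree, matrix, clades, fractions=(fraction,), reps=reps, B=B, seed=seed
    )
    summary = result.summary()
    return {
        "flip_rate": float(summary["flip_rate"].iloc[0]),
        "mean_abs_delta_D": float(summary["mean_abs_delta_D"].iloc[0]),
        "baseline_D": result.baseline.rows[0].result.D,
        "reps": reps,
        "fraction": fraction,
    }
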