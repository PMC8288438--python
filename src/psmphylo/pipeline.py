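"""End-to-end orchestration: config, reporting, annotation export, and the
trait lineages-through-time surrogate.

``run_full_analysis`` wires the stages together — align the trait matrix to
the tree, compute distribution summaries, run the clade x class signal
screen and the subsampling-robustness experiment, count trait-bearing
lineages through time, and export a ring-annotation table — writing every
table plus a manifest sufficient to re-run the analysis bit-identically.

The lineages-through-time table is a deliberately simple surrogate for
"when did trait-bearing lineages proliferate": at each age t it counts the
branches crossing t whose descendant tips include at least one presence
(a Dollo-style minimal mapping — a branch qualifies iff the trait survives
somewhere below it).  It is a descriptive summary, not an ancestral-state
reconstruction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .screen import (
    RobustnessResult,
    ScreenTable,
    clade_presence_summary,
    run_robustness,
    run_screen,
)
from .traitkit import (
    TraitMatrix,
    align_to_tree,
    class_prevalence,
    read_matrix_tsv,
    richness_histogram,
    usable_family_count,
)
from .treekit import (
    CladeDefinition,
    Phylogeny,
    collapse_to_families,
    read_clade_definitions,
    read_family_mapping,
    read_newick,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "run_full_analysis",
    "trait_lineages_through_time",
    "export_tree_annotation",
    "DEFAULT_PALETTE",
    "NEUTRAL_COLOR",
]

#: Gray marks "absent or unknown" in annotation exports.
NEUTRAL_COLOR = "#bdbdbd"

_PALETTE_CYCLE = [
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3",
    "#ff7f00", "#a65628", "#f781bf", "#17becf",
]


def DEFAULT_PALETTE(classes: Sequence[str]) -> dict[str, str]:
    """A fixed color per class, cycling through a colorblind-aware list."""
    return {c: _PALETTE_CYCLE[i % len(_PALETTE_CYCLE)] for i, c in enumerate(classes)}


@dataclass
class AnalysisConfig:
    """Declarative description of one full analysis run."""

    tree: str
    traits: str
    clades: str | None = None
    mapping: str | None = None
    synonyms: str | None = None
    out_dir: str = "results"
    B: int = 1000
    seed: int = 0
    alpha: float = 0.05
    min_tips: int = 25
    fractions: tuple[float, ...] = (0.5, 0.7, 0.8, 0.95)
    reps: int = 10
    stratified_subsampling: bool = False
    p_adjust: bool = False  # Benjamini-Hochberg across the grid (off by default)
    plus_one_p: bool = False
    ltt_grid_points: int = 101

    def validate(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for f in self.fractions:
            if not 0 < f <= 1:
                raise ValueError(f"fraction {f} outside (0, 1]")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "fractions" in raw:
            raw["fractions"] = tuple(float(x) for x in raw["fractions"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = dataclasses.asdict(self)
        data["fractions"] = list(self.fractions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class ReportBundle:
    """Everything one run produced, with a manifest that re-runs it."""

    config: AnalysisConfig
    tree: Phylogeny
    matrix: TraitMatrix
    summaries: dict
    screen: ScreenTable
    robustness: RobustnessResult | None
    ltt: pd.DataFrame
    annotation: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# Temporal surrogate
# ---------------------------------------------------------------------------


def trait_lineages_through_time(
    tree: Phylogeny,
    matrix: TraitMatrix,
    class_name: str,
    time_grid: Sequence[float],
) -> pd.DataFrame:
    """Branches crossing each age that lead to >=1 present tip.

    At t = 0 the count equals the class prevalence restricted to tree tips;
    it is non-increasing in t and bounded by the plain lineage count.
    """
    if class_name not in matrix.classes:
        raise KeyError(f"unknown class {class_name!r}")
    ages = tree.ages()
    root_age = ages[id(tree.root)]
    binary = matrix.binary()[class_name]
    present_below: dict[int, bool] = {}
    for node in tree.postorder():
        if node.is_tip:
            present_below[id(node)] = bool(
                node.label in binary.index and binary[node.label] == 1
            )
        else:
            present_below[id(node)] = any(present_below[id(c)] for c in node.children)
    any_present = present_below[id(tree.root)]
    rows = []
    nonroot = [n for n in tree.preorder() if n is not tree.root]
    for t in time_grid:
        count = 1 if (t >= root_age and any_present) else 0
        for node in nonroot:
            if ages[id(node.parent)] > t >= ages[id(node)] and present_below[id(node)]:
                count += 1
        rows.append({"t": float(t), "lineages": count})
    return pd.DataFrame(rows, columns=["t", "lineages"])


# ---------------------------------------------------------------------------
# Annotation export
# ---------------------------------------------------------------------------


def export_tree_annotation(
    tree: Phylogeny,
    matrix: TraitMatrix,
    palette: Mapping[str, str] | None = None,
    path: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """Ring-annotation table: one row per family (tree tip order), one color
    column per class; absent/unknown cells carry the neutral gray.

    The output is a plain TSV any annotation-aware tree viewer can ingest
    as a per-tip color strip.
    """
    if palette is None:
        palette = DEFAULT_PALETTE(matrix.classes)
    missing = [c for c in matrix.classes if c not in palette]
    if missing:
        raise ValueError(f"palette missing classes: {missing}")
    aligned, _ = align_to_tree(matrix, tree)
    binary = aligned.binary()
    data = {
        cls: [palette[cls] if binary.at[f, cls] == 1 else NEUTRAL_COLOR
              for f in aligned.families]
        for cls in aligned.classes
    }
    df = pd.DataFrame(data, index=pd.Index(aligned.families, name="family"))
    if path is not None:
        df.to_csv(path, sep="\t")
    return df


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def _bh_adjust(table: ScreenTable) -> pd.DataFrame:
    """Benjamini-Hochberg adjusted shuffle p-values across estimated cells."""
    from statsmodels.stats.multitest import multipletests

    df = table.to_dataframe()
    mask = df["skip_reason"] == ""
    adjusted = pd.Series(np.nan, index=df.index)
    if mask.sum() > 0:
        _, p_adj, _, _ = multipletests(df.loc[mask, "p_random"], method="fdr_bh")
        adjusted.loc[mask] = p_adj
    df["p_random_bh"] = adjusted
    return df


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the whole pipeline per the config; write all outputs + manifest."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)

    tree = read_newick(config.tree)
    if config.mapping:
        tree = collapse_to_families(tree, read_family_mapping(config.mapping))
    matrix = read_matrix_tsv(config.traits)
    if config.synonyms:
        matrix = matrix.rename_families(read_family_mapping(config.synonyms))
    aligned, align_report = align_to_tree(matrix, tree)

    if config.clades:
        clades = read_clade_definitions(config.clades)
    else:
        # whole-tree screen when no clade roster is supplied
        clades = [
            CladeDefinition("all", members=frozenset(tree.tip_labels))
        ]

    summaries = {
        "n_families": len(aligned.families),
        "n_classes": len(aligned.classes),
        "usable_families": usable_family_count(aligned),
        "prevalence": {c: class_prevalence(aligned, c) for c in aligned.classes},
        "richness_histogram": richness_histogram(aligned),
        "dropped_tree_only": align_report.tree_only,
        "dropped_matrix_only": align_report.matrix_only,
    }

    table = run_screen(
        tree, aligned, clades,
        B=config.B, seed=config.seed, min_tips=config.min_tips,
        alpha=config.alpha, plus_one=config.plus_one_p,
    )
    screen_df = _bh_adjust(table) if config.p_adjust else table.to_dataframe()

    robustness = run_robustness(
        tree, aligned, clades,
        fractions=config.fractions, reps=config.reps, B=config.B,
        seed=config.seed, min_tips=config.min_tips, alpha=config.alpha,
        stratify_by_class=config.stratified_subsampling,
    )
    presence = clade_presence_summary(tree, aligned, clades)

    try:
        grid_max = tree.ages()[id(tree.root)]
        grid = np.linspace(0.0, grid_max, config.ltt_grid_points)
        ltt_frames = []
        for cls in aligned.classes:
            frame = trait_lineages_through_time(tree, aligned, cls, grid)
            frame.insert(0, "class", cls)
            ltt_frames.append(frame)
        ltt = pd.concat(ltt_frames, ignore_index=True)
    except ValueError as exc:
        logger.warning("skipping lineages-through-time: %s", exc)
        ltt = pd.DataFrame(columns=["class", "t", "lineages"])

    annotation = export_tree_annotation(tree, aligned)

    # -- write everything --------------------------------------------------
    out = config.out_dir
    with open(os.path.join(out, "summaries.json"), "w") as fh:
        json.dump(summaries, fh, indent=2, sort_keys=True)
    screen_df.to_csv(os.path.join(out, "screen.tsv"), sep="\t", index=False)
    robustness.summary().to_csv(
        os.path.join(out, "robustness.tsv"), sep="\t", index=False
    )
    presence.to_csv(os.path.join(out, "clade_presence.tsv"), sep="\t", index=False)
    ltt.to_csv(os.path.join(out, "ltt.tsv"), sep="\t", index=False)
    annotation.to_csv(os.path.join(out, "annotation.tsv"), sep="\t")
    config.to_yaml(os.path.join(out, "config.resolved.yaml"))

    manifest = {
        "psmphylo_version": __version__,
        "seed": config.seed,
        "B": config.B,
        "tree_hash": table.metadata["tree_hash"],
        "matrix_hash": table.metadata["matrix_hash"],
        "inputs": {
            "tree": config.tree,
            "traits": config.traits,
            "clades": config.clades,
            "mapping": config.mapping,
            "synonyms": config.synonyms,
        },
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return ReportBundle(
        config=config,
        tree=tree,
        matrix=aligned,
        summaries=summaries,
        screen=table,
        robustness=robustness,
        ltt=ltt,
        annotation=annotation,
        manifest=manifest,
    )
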