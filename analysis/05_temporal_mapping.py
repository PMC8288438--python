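#!/usr/bin/env python
"""Trait-bearing lineages through time, per class.

For each class, counts the branches crossing each age whose descendant
tips include at least one presence — a minimal (Dollo-style) temporal
mapping of when lineages carrying each class proliferated.  Also exports
the ring-annotation color table for external tree viewers.

Reads results/study/, writes results/ltt.tsv and results/annotation.tsv.
"""

import pathlib

import numpy as np
import pandas as pd

from psmphylo import read_matrix_tsv, read_newick
from psmphylo.pipeline import export_tree_annotation, trait_lineages_through_time
from psmphylo.traitkit import align_to_tree

GRID_POINTS = 41
ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    tree = read_newick(ROOT / "study" / "tree.nwk")
    matrix, _ = align_to_tree(read_matrix_tsv(ROOT / "study" / "matrix.tsv"), tree)
    root_age = tree.ages()[id(tree.root)]
    grid = np.linspace(0.0, root_age, GRID_POINTS)
    frames = []
    for cls in matrix.classes:
        frame = trait_lineages_through_time(tree, matrix, cls, grid)
        frame.insert(0, "class", cls)
        frames.append(frame)
        half = frame[frame["lineages"] <= frame["lineages"].iloc[0] / 2]["t"].iloc[0]
        print(f"{cls}: {frame['lineages'].iloc[0]} lineages at present; "
              f"halved by age {half:.2f}")
    pd.concat(frames, ignore_index=True).to_csv(ROOT / "ltt.tsv", sep="\t", index=False)
    export_tree_annotation(tree, matrix, path=ROOT / "annotation.tsv")
    print(f"wrote {ROOT/'ltt.tsv'} and {ROOT/'annotation.tsv'}")


if __name__ == "__main__":
    main()
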