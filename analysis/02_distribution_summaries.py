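#!/usr/bin/env python
"""Distribution summaries of the synthetic study matrix.

Reports how many families have usable data (>= 1 class present), the
per-class prevalence (the preset reproduces the published family counts by
construction), and the richness histogram (families by number of classes).

Reads results/study/, writes results/summaries.json.
"""

import json
import pathlib

from psmphylo import read_matrix_tsv
from psmphylo.traitkit import class_prevalence, richness_histogram, usable_family_count

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    matrix = read_matrix_tsv(ROOT / "study" / "matrix.tsv")
    summary = {
        "n_families": len(matrix.families),
        "n_classes": len(matrix.classes),
        "usable_families": usable_family_count(matrix),
        "prevalence": {c: class_prevalence(matrix, c) for c in matrix.classes},
        "richness_histogram": richness_histogram(matrix),
    }
    out = ROOT / "summaries.json"
    out.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    print(f"usable data for {summary['usable_families']} of "
          f"{summary['n_families']} families")
    prev = summary["prevalence"]
    top = max(prev, key=prev.get)
    print(f"most widespread class: {top} ({prev[top]} families); wrote {out}")


if __name__ == "__main__":
    main()
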