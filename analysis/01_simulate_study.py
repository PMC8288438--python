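#!/usr/bin/env python
"""Generate the synthetic study dataset every later step consumes.

Materializes the 437-family x 8-class preset — a Yule family-level tree and
a presence/absence matrix whose per-class family counts match the published
survey (flavonoids in 245 families down to quinones in 82) — plus a small
4-regime calibration study with known generating regimes per class.

Writes results/study/ (tree.nwk, matrix.tsv, truth.json) and
results/calibration_study/.
"""

import json
import pathlib

from psmphylo.synthdata import RegimeSpec, make_synthetic_study, paperlike_study

SEED = 2024
ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main():
    study = paperlike_study(seed=SEED)
    study.write(ROOT / "study")
    print(f"wrote {len(study.matrix.families)} families x "
          f"{len(study.matrix.classes)} classes to {ROOT/'study'}")

    cal = make_synthetic_study(
        200,
        {
            "clumped_class": RegimeSpec("clumped", 0.3),
            "brownian_class": RegimeSpec("brownian_threshold", 0.3),
            "random_class": RegimeSpec("random", 0.3),
            "overdispersed_class": RegimeSpec("overdispersed", 0.3),
        },
        seed=SEED + 1,
    )
    cal.write(ROOT / "calibration_study")
    print(f"wrote 4-regime calibration study (200 families) to {ROOT/'calibration_study'}")


if __name__ == "__main__":
    main()
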