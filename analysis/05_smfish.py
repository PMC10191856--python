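#!/usr/bin/env python
"""smFISH quantification: nascent counts, active fraction, cell cycle.

Simulates a half-silent / half-expressing population with bimodal DAPI
content, counts nascent RNAs at each cell's transcription site (brightest
nuclear spot over the median cytoplasmic single-RNA intensity), applies
the >= 5-RNA activity rule, and classifies cell-cycle stage from a
two-component Gaussian mixture of the DAPI sums.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from burstepi import pipelines as pl
from burstepi.smfish_quant import summarize_replicates

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    replicates = [pl.smfish_study(n_cells=2000, seed=s) for s in (0, 1, 2)]
    for i, r in enumerate(replicates):
        print(f"replicate {i}: active fraction {r['active_fraction']:.3f} "
              f"(truth {r['true_active_fraction']:.3f}), "
              f"mean nascent of active {r['mean_nascent_active']:.2f}, "
              f"stage-call accuracy {100*r['stage_accuracy']:.1f}%")
    summary = summarize_replicates(replicates)
    print("\nacross replicates (mean +- s.e.m.):")
    print(summary.to_string(index=False))

    BASE.mkdir(exist_ok=True)
    summary.to_csv(BASE / "smfish_summary.csv", index=False)
    with open(BASE / "smfish_replicates.json", "w") as fh:
        json.dump([{k: v for k, v in r.items() if k != "gmm"} for r in replicates], fh, indent=2)
    print(f"\nwrote {BASE/'smfish_summary.csv'}")


if __name__ == "__main__":
    main()
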