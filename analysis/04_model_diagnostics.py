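#!/usr/bin/env python
"""Model evaluation: goodness-of-fit, NPDE and VPC tables.

Under a correct model the NPDE are standard normal (mean ~0, variance ~1)
and the observed concentration percentiles track their simulated 90%
prediction intervals. Writes gof.csv (per-observation predictions + NPDE)
and vpc.csv (binned percentile bands) for plotting.
"""

import logging
from pathlib import Path

import pandas as pd

from posapk.pipeline import run_pipeline

logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")
OUT = Path("results/pipeline")

manifest = run_pipeline({"seed": 1, "diagnostics": {"K": 500}}, outdir=OUT,
                        stages=("simulate", "fit", "screen", "diagnose"))

print(f"\nNPDE summary: mean {manifest['npde_summary']['mean']:+.3f}, "
      f"variance {manifest['npde_summary']['var']:.3f} "
      "(standard normal under a correct model)")
v = pd.read_csv(OUT / "vpc.csv")
med = v[v["percentile"] == 50.0]
inside = ((med["observed"] >= med["pi_lo"])
          & (med["observed"] <= med["pi_hi"])).mean()
print(f"VPC: observed medians inside the 90% PI in {inside:.0%} of bins")
print(f"tables: {OUT / 'gof.csv'}, {OUT / 'vpc.csv'}")
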