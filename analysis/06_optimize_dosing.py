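#!/usr/bin/env python
"""Stratified dose search: smallest once-daily dose per (indication, age)
stratum with PTA >= 90%.

Evaluates 100/200/300/400 mg per stratum on a common set of simulated
individuals. With attainment judged on the observation scale (troughs
carrying the 0.29 proportional error) the therapy strata fall short of the
0.90 criterion at the published doses — see docs/methods.md for why the
published 200/300/300/400 map is not reproducible under a strict
per-stratum rule on that scale (the published therapy/over-60 PTA itself
is 89%) — while on the error-free model scale prophylaxis de-escalates
further. Both scales are printed for comparison.
"""

import json
import logging
from pathlib import Path

import pandas as pd

from posapk.pipeline import run_pipeline

logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")
OUT = Path("results/pipeline")

for scale in ("observation", "model"):
    manifest = run_pipeline(
        {"seed": 1, "optimize": {"trough_scale": scale}},
        outdir=OUT / scale, stages=("simulate", "optimize"))
    print(f"\n--- trough scale: {scale} ---")
    tab = pd.read_csv(OUT / scale / "dose_pta.csv").dropna()
    piv = tab.pivot_table(index=["indication", "stratum"], columns="dose",
                          values="pta") * 100
    print(piv.round(1))
    reg = json.loads((OUT / scale / "regimen.json").read_text())
    print("selected doses (mg):", reg["regimen"])
    if reg["unattainable"]:
        print("strata below min PTA at every candidate:",
              reg["unattainable"])
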