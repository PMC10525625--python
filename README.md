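# posapk — population pharmacokinetics of posaconazole in lung-transplant recipients

Lung-transplant recipients receive posaconazole tablets for antifungal
prophylaxis or therapy, monitored through sparse trough-level sampling
(therapeutic drug monitoring, TDM). The approved label dose is a uniform
300 mg once daily, yet the PK/PD targets differ by intent — a steady-state
trough above 0.7 mg/L for prophylaxis and above 1.25 mg/L for therapy
(equivalently a 24-h AUC/MIC ≥ 200 at the EUCAST *Aspergillus* breakpoint
MIC of 0.125 mg/L) — so a single dose cannot serve every patient equally.
`posapk` implements the full analysis pipeline for this problem: a
population PK model fitted to sparse TDM data, covariate screening, model
diagnostics, and Monte Carlo simulation of probability of target
attainment (PTA) to derive an age- and indication-stratified dosing
regimen.

## Model

Structural model: one-compartment disposition with first-order absorption
and elimination, parametrized by the apparent oral parameters (F is
unidentifiable after oral dosing and absorbed into them):

    C(t) = D·Ka / (V·(Ka − ke)) · (e^{−ke·t} − e^{−Ka·t}),   ke = CL/V

with Ka fixed at 0.8 h⁻¹, derived by root-solving the peak-time relation
t_max = (ln Ka − ln ke)/(Ka − ke) from the label half-life (26–31 h) —
elimination-phase TDM sampling cannot inform Ka.

Population model (log-normal inter-individual variability, uncentered age
covariate on clearance, proportional residual error):

    log Ka_i   = log Ka_pop                     + η_Ka,i
    log Vd/F_i = log Vd/F_pop                   + η_V,i
    log CL/F_i = log CL/F_pop + β_age·age_i     + η_CL,i
    y_ij       = C(t_ij; θ_i) · (1 + b·ε_ij)

Final estimates (the package defaults): Vd/F 386.35 L, CL/F 8.8 L/h at the
age-0 intercept with β_age = −0.009 per year (≈ −0.9 %/year, i.e.
≈ 5.3 L/h for a typical 56-year-old), ω_Ka 3.43, ω_V 0.45, ω_CL 0.36,
b = 0.29. Estimation is by SAEM (stochastic approximation EM with an MCMC
E-step), with importance-sampling and Laplace backends for the objective
function value (OFV = −2 log-likelihood) and empirical-Bayes estimates of
the per-subject random effects.

## Layout

- `src/posapk/` — the library: `pk` (closed-form kinetics), `population`
  (hierarchical layer), `cohort` (virtual cohorts + TDM dataset
  simulation), `estimation` (SAEM/OFV/EBE), `covariates` (screening +
  stepwise building), `diagnostics` (NPDE, VPC), `pta` (Monte Carlo target
  attainment and dose optimization), `io`/`pipeline`/`cli` (NONMEM-style
  CSV I/O, config, orchestration).
- `analysis/01…06_*.py` — numbered drivers that narrate the analysis and
  write tables under `results/`.
- A thin CLI mirrors the drivers: `posapk simulate-cohort | fit | screen |
  diagnose | pta | optimize-dose | run-all`.

## Worked example

```sh
python analysis/05_pta_simulation.py
```

simulates 500 replicates of a 32-subject virtual cohort (16,000 virtual
patients per scenario) under the final model and prints, among others:

```
    regimen  indication  stratum  pta_trough  pta_auc  auc_median
uniform-300 prophylaxis  overall        95.8     98.5        56.1
uniform-300     therapy  overall        80.1     98.7        56.2
   proposed prophylaxis  overall        93.9     96.0        49.5
   proposed     therapy  overall        87.9     99.6        68.1
   proposed prophylaxis  over-60        90.5     91.2        40.5
   proposed     therapy  over-60        85.2     99.2        61.0
```

Reading: at the uniform 300 mg dose, 95.8% of virtual patients meet the
prophylaxis trough target but only 80.1% meet the stricter therapy target;
under the proposed stratified map (200 mg prophylaxis/over-60, 300 mg
prophylaxis/under-60 and therapy/over-60, 400 mg therapy/under-60) therapy
attainment rises to 87.9% (Fisher exact p < 1e-80 vs uniform) while
over-60 prophylaxis patients are spared a third of the dose at a median
AUC₂₄ of 40.5 mg·h/L, still comfortably above the 25 mg·h/L AUC/MIC bound.
`analysis/06_optimize_dosing.py` prints the per-stratum PTA-by-dose tables
behind the dose search on both trough scales (with and without the
residual-error layer); see `docs/methods.md` for how the scale choice
interacts with the 90% attainment criterion.

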