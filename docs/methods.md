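# Methods

## Structural and statistical model

The concentration model is the one-compartment first-order
absorption/elimination (Bateman) solution with apparent oral parameters
(Ka in 1/h, Vd/F in L, CL/F in L/h; time in hours, amounts in mg,
concentrations in mg/L throughout the library — unit conversion is an I/O
concern only). Multiple dosing uses the closed-form geometric accumulation
of the two exponentials, for a finite dose train as well as for the
infinite-history steady state; the steady-state trough is the profile
value at t = τ, and the steady-state 24-h AUC is exactly dose/CL. When
|Ka − ke|/ke < 1e−6 the Bateman form is replaced by its analytic limit
D·Ka·t·e^{−Ka·t}/V to avoid catastrophic cancellation; vectorized code
paths instead nudge Ka off the removable singularity by 1e−5 relative,
which is accurate to ~1e−5 and far below every tolerance used.

Ka is fixed at 0.8 1/h. It is derived by inverting
t_max = (ln Ka − ln ke)/(Ka − ke) on the fast-absorption branch (Ka > ke):
on that branch t_max decreases monotonically from 1/ke to 0, so `solve_ka`
brackets a unique root and rejects peak times outside (t_min(cap), 1/ke)
with the feasible range in the error message. The label t_max that pins
0.8 exactly is not published; the derivation is validated by round-trip
(back-computed t_max for half-lives 26–31 h reproduces 0.80 to two
decimals).

Hierarchy: log-normal inter-individual variability on all three
parameters, a linear age term on log CL/F, proportional residual error
y = c·(1 + b·ε) floored at zero (concentrations are physical; the flooring
matters only in the far tail at b = 0.29).

### The age covariate is uncentered

`cl_pop` = 8.8 L/h is the intercept at age 0, so a typical 56-year-old has
CL/F = 8.8·e^{−0.009·56} ≈ 5.3 L/h. This reading is forced by the reported
exposures: over-60 patients at 200/300 mg have median AUC₂₄ ≈ 40/60 mg·h/L,
which requires CL/F ≈ 5.0 L/h at age ~63 — exactly what the uncentered
equation gives. A mean-centered reading (8.8 L/h at the cohort mean age)
would put those medians near 23/34 mg·h/L and is inconsistent. The
verbal gloss "decreases by 0.009 L/h per year" is treated as a loose
description of the log-scale coefficient (≈0.9%/year).

ω_Ka = 3.43 is retained when simulating (faithful to the reported model)
even though it is barely informed by elimination-phase data; it mostly
adds a slow-absorption ("flip-flop") subpopulation with somewhat higher
troughs. No cap is applied to the η draws by default.

## Virtual cohorts and TDM sampling design

Continuous covariates are drawn from Beta distributions scaled to the
published range and fitted so that the scaled median and IQR width match
the published summaries exactly (two shape parameters, two constraints);
individual quartile positions then land where the Beta family puts them,
within ~2%. Covariates are mutually independent — only marginal summaries
are published — with an optional Gaussian-copula correlation hook on
`CohortSpec`. Categorical covariates use the reported frequencies (10/32
female; transplant indications 3/7/13/7/1/1 for CF/IPF/ILD/COPD/asthma/
chronic aspergillosis; calcineurin inhibitor 32/32, mycophenolate 31/32,
acid suppressants 29/32). Treatment duration uses the reported median 40
and range 10–1123 days with a synthetic IQR stand-in of (20, 120) days.

The TDM design emulates the study: once-daily 300 mg from time zero,
samples only in the elimination phase (default window 12–24 h after the
last dose, which must open after the ~4.6 h absorption peak), on days 4–60
of treatment. Per-subject sample counts follow a geometric law truncated
to [1, 12] with mean 2.5 — reproducing the reported average (≈80 total
observations for 32 subjects); a uniform draw on [1, 12] would average 6.5
and was therefore not used. Which subjects receive many samples is
unknown; the geometric stand-in is documented, not claimed. Observations
below the 0.1 mg/L LLOQ are flagged BLQ, stored at the LLOQ, and excluded
from estimation with a warning — at typical troughs (>1 mg/L) this is a
rare event, so simple exclusion is the default. Dose adjustment in
response to simulated TDM values is not emulated (no adjustment rule is
published); the dose train is constant per subject.

## Estimation

SAEM with a per-subject Metropolis-Hastings kernel on η: each iteration
runs one independent proposal from the prior (the prior densities cancel
in the acceptance ratio; this handles the broad, sometimes bimodal η_Ka
posteriors that sparse elimination-phase data produce) followed by two
adaptive random-walk sweeps targeting ~30% acceptance. Sufficient
statistics (per-subject φ and φ², and the summed squared proportional
residuals) are stochastically averaged with step 1 during the exploratory
phase and 1/k during smoothing; default 400 + 200 iterations. M-step:
fixed effects by least squares of the φ statistics on the per-dimension
covariate design; ω² and b² from the averaged second moments, with a
simulated-annealing floor (0.95 per iteration) during exploration to
prevent premature variance collapse. Ka_pop is frozen by default.

Degenerate random effects: dimensions with ω fixed at zero (or collapsed
below ω = 0.02) receive no information through the φ regression, so their
intercepts are updated by a damped Newton step on the observed-data
likelihood — the EM update in the degenerate limit. If *all* ω are zero
the marginal model is a plain proportional-error nonlinear regression and
`fit` dispatches to iteratively reweighted least squares.

OFV: per-subject importance sampling (default 1,000 draws) with a Gaussian
proposal at the MAP η and Laplace covariance, reported with its Monte
Carlo SE; a deterministic Laplace backend serves fast nested comparisons.
ω = 0 dimensions are collapsed analytically. RSEs come from the empirical
Fisher information assembled from per-subject marginal scores (posterior
expectations of the complete-data score over conditional MH samples);
intercept SEs are reported on the natural scale. η-shrinkage is
1 − SD(EBE)/ω.

Identifiability caveats, verified in simulation: with elimination-phase
sampling, V and Ka variability are partly confounded (ω_V biased up,
ω_Ka down, each within ~25% at n = 200), and the uncentered age
parametrization makes (log CL/F_pop, β_age) strongly collinear — their
joint combination at the observed ages is precise while β alone carries
~50–60% RSE, consistent with the reported estimate's RSE of 63%.

## Covariate analysis

Screening: Pearson correlation (continuous) or one-way ANOVA F test
(categorical) of each candidate against the per-subject log-parameter
estimates, two-sided, no multiple-testing correction (matching the
original workflow). When η-shrinkage exceeds 30% the screen runs on
conditional-distribution samples (median p over 20 single-draw screens)
instead of MAP modes, which shrinkage would otherwise bias toward null.

Stepwise building: forward inclusion in ascending screening-p order,
candidate kept iff ΔOFV > 3.84 (χ²₁ at 0.05), then a backward pass.
Nested refits are warm-started from the current model's estimates and
compared with the deterministic Laplace OFV; without warm starting, the
OFV difference between independently run SAEM fits on 32–40-subject data
carries ±10-point run-to-run noise that swamps the criterion. Multi-level
(>2) categorical covariates are screened but not entered linearly; the
functional form on inclusion is linear on the log-parameter scale.

## Diagnostics

NPDE: K (default 1000) simulated replicates of each subject's design;
per-subject decorrelation by the Cholesky factor of the empirical
simulated covariance (ridge-regularized if singular); ranks with uniform
tie-jitter mapped through Φ⁻¹, clipped to [1/(2K), 1 − 1/(2K)]. VPC:
observed 10/50/90th percentiles per time-after-dose bin (quantile bins,
default 6; bins under 5 observations merged into a neighbour) against the
90% prediction interval of the same percentiles across replicates; a
prediction-corrected variant is available (off by default) for
mixed-dose datasets. Note the VPC hit rate is itself a statistic with
expectation equal to the nominal level, so calibration checks use a
two-sided band around 90%, not a one-sided bound at it.

## PTA simulation and dose optimization

Each scenario simulates `n_replicates` (default 500) copies of the
32-subject cohort: fresh η per virtual patient, steady-state trough in
closed form, AUC₂₄ = dose/CL. Trough attainment is assessed by default on
the observation scale — the model trough perturbed by one proportional-
error draw — because only that scale reproduces the reported attainment
percentages (therapy at uniform 300 mg: ~80% vs ~87% error-free); AUC
attainment is always model-based. The age boundary is "under 60" =
age < 60. A `trough_scale` switch exposes the error-free alternative
everywhere.

`optimize_regimen` returns, per (indication, age stratum), the smallest
candidate dose (default {100, 200, 300, 400} mg) whose stratum PTA
reaches `min_pta` (default 0.90), evaluating all candidates on one set of
simulated individuals (exposure is linear in dose), so the search is
deterministic given the seed; strata that fail at every candidate are
flagged with their best achievable PTA.

### Why the published 200/300/300/400 map is not recovered by a strict rule

Under this reconstruction the strict per-stratum PTA ≥ 0.90 criterion does
not select the published map on either trough scale: with residual error
included, therapy/over-60 at 300 mg sits at ~84–86% (the original report
itself lists 89% there — already below 0.90) and therapy/under-60 at
400 mg at ~89%; error-free, prophylaxis/under-60 already clears 0.90 at
200 mg (~92%) and would be de-escalated below the published 300 mg. Every
single-rule reading misses exactly one cell, so the original selection
evidently involved judgment beyond a hard per-stratum cutoff (e.g.
rounding, or an overall-per-indication view). The optimizer implements
the plain rule and reports the discrepancy rather than encoding a rule
reverse-engineered to match. All reported attainment *values* are
reproduced within ±5 percentage points and exposures within ±15%.

## Problem sizes and numerical choices

The test suite runs the heavy simulations at reduced scale chosen for
desk-speed iteration: parameter recovery at 10 replicates of 200 subjects
× 6 samples with 300+200 SAEM iterations, screening power at 20
replicates, NPDE/VPC calibration at K = 200–500, null stepwise behaviour
at 50 replicates of 40 sparse subjects. The headline PTA simulation runs
at full published scale (500 × 32) — it is closed-form arithmetic and
takes seconds. All randomness is generator-passed; every test and script
is deterministic given its seed.

## Known limitations

- Covariates are generated independently; any real correlation (e.g.
  height-weight-BSA) is absent unless supplied via the correlation hook.
- The actual patient ages are unknown; all cohort-level results carry
  population-reconstruction error, absorbed by the stated tolerances.
- ω_Ka is estimable only weakly from elimination-phase designs; its
  estimate (and ω_V's) should be interpreted with the confounding noted
  above.
- BLQ handling is exclusion-only; likelihood-based (M3-type) BLQ
  treatment is out of scope at this LLOQ.
- Inter-occasion variability, covariance between random effects, and
  two-compartment disposition are deliberately unsupported (rejected in
  the model-building this package reproduces).
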