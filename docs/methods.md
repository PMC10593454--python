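# Methods

This note documents the models, the numerical and design choices behind
them, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Pharmacokinetic model

Disposition is a linear two-compartment model (central V, peripheral V2,
clearance CL, inter-compartmental clearance Q) under superposed zero-order
IV infusions. Clearance-like parameters scale allometrically with
(WT/70)^0.75 and volumes with (WT/70). Three multiplicative factors act on
clearance:

- **Renal function** `Fren = (CLCr/CLCr_TV)^λ`, with
  `CLCr = RCr/Cr · exp(−k_tox·t)` and `RCr = 64.2·exp(k_Cr·(age−30))` mg/h.
  The slope k_Cr is +0.0193/yr below age 30 and −0.0127/yr above, so
  creatinine production — and with it typical CLCr — peaks at age 30.
  k_tox (0.00598/day) encodes the gradual loss of creatinine clearance
  over a treatment course attributed to vancomycin nephrotoxicity; its
  clock `t` counts days since the first dose and is zero for dose
  selection at treatment start.
- **Maturation** `Fmat = PMA^γ/(PMA50^γ+PMA^γ)`, applied only under 4
  years of age (PMA50 = 43.9 weeks, γ = 2.08). Exactly 1 from age 4.
- **Covariates** `COVCL = exp(k_BUN(BUN−15))·(1+θ_FEM·FEM)·(1+θ_DM·DM)·(1+θ_REN·REN)`
  and, on the central volume, `COVV = exp(k_V(age−40))` (≈1%/yr growth).

The reference creatinine that defines `CLCr_TV` is not part of the
published estimates; it is exposed as `cr_ref` and defaults to 1.0 mg/dL,
under which `CLCr_TV = 64.2` and the regenerated nomograms match the
published tables (see below). Between-subject variability is log-normal on
CL (ω = 0.291) and V2 (ω = 1.01); printed CV% values are read as 100×SD of
the log-scale effect. Residual error is combined and stratified by sample
type (proportional SD 0.178/0.110 and additive SD 0.956/4.47 mg/L for
trough/peak).

Concentrations are evaluated in closed form from the bi-exponential
disposition eigensystem (mono-exponential when Q = 0); an independent
piecewise ODE integration (`ode_concentrations`, LSODA at rtol 1e−10) is
kept as a cross-check and agrees to better than 1e−6 relative. Steady-state
trough (start of infusion) and peak (end of infusion) come from the
geometric-series superposition limit, and AUC24 from the linear-kinetics
identity daily dose/CL, verified against trapezoidal integration to 0.1%.

Units: hours inside all models; age in years, PMA in weeks, the k_tox
clock in days; conversions live in `types.py`.

## CRP pharmacodynamic model

Five states: proliferation, two transit compartments, circulating CRP and
a latent disease severity D. Production and all transfers share the rate
k_tr (0.0129/h, +0.0058 with pneumonia), so the chain's mean transit time
is 3/k_tr (9.7 d / 6.7 d). CRP is eliminated at k_CRP, fixed at
ln 2/19 h = 0.0365/h from the 19-h CRP half-life; one published record of
this constant reads 0.365, which is inconsistent with both the stated
half-life and the stated fixing rationale, so 0.0365 is adopted (it
remains configurable). Severity follows dD/dt = k_D·D·(1 − α·AUC(t)):
exponential growth (doubling time ln 2/k_D ≈ 15 d) until cumulative
exposure crosses 1/α ≈ 4,184 mg·h/L, then accelerating collapse.

Two decisions the source model leaves open:

- **Exposure metric.** AUC(t) is the cumulative vancomycin AUC from
  treatment start (∫₀ᵗ C ds). A per-interval AUC would make the drug
  effect constant and could not produce dose-dependent divergence after
  ~10 days; with the cumulative reading, the 2 g/day typical adult crosses
  E_drug = 1 at ≈224 h, matching the reported ~240-h divergence onset.
- **Initialization.** Compartments start at the disease steady state
  consistent with the baseline CRP0 = 110 mg/L: all chain states equal
  CRP0·k_CRP/k_tr and D0 = (CRP0·k_CRP/k_tr − 1)/S_CRP (≈3.04 without
  pneumonia), making every derivative zero at t = 0 in the absence of
  drug.

Integration uses LSODA at rtol 1e−8 / atol 1e−10; halving the reporting
step moves the normalization time by <1%. `time_to_normalization` returns
the first time after the CRP maximum at which CRP lies in [1, 10] mg/L and
never again rebounds above 10; falling *below* 1 mg/L later does not
disqualify the entry, because the model's drug-free healthy baseline
(k_tr/k_CRP ≈ 0.35 mg/L) sits below the normal range, so every successful
trajectory eventually undershoots it. Under the 2 g/day reference regimen
the typical adult normalizes at ≈1,290 h, within the ±20% band around the
reported ≈1,100 h that the unstated initialization conventions warrant.

A fast exposure shortcut `linear_auc_approximation` (daily dose/CL · t/24)
matches the steady-state accrual *rate* within 2% after two days, but its
cumulative value runs ahead of the true exposure by the accumulation
deficit, asymptotically C̄·MRT = (daily dose/24/CL)·(V_ss/CL) ≈ 556 mg·h/L
for the typical adult — about 64% of the adult AUC sits in the ~27-h
terminal phase, so this deficit decays slowly. Passing `v_ss` subtracts
the asymptotic deficit and brings cumulative agreement within 2% from
roughly day 10.

## Dose optimizer and nomograms

For each covariate scenario the optimizer simulates the typical subject
(η = 0, t = 0) on 1-h infusions every 6 h, scans the dose grid (adults
0.2–6.0 g/day by 0.2; pediatrics 5–120 mg/kg/day by 5), discards doses
whose peak reaches 40 mg/L, and picks the remaining dose with trough
closest to the age-banded target, lower dose on ties. Concentrations are
linear in dose, so one unit-dose simulation prices the whole grid; the
full adult table builds in well under a second.

The published tables were generated with an unstated simulation horizon
and trough-sampling time. Reproducing them cell-by-cell identifies the
conventions: for adults, a 20-dose (120-h) course with the trough read
0.75 h before the next dose reproduces 96.7% of cells exactly (the rest
within one 0.2 g/day step); for the pediatric and under-4 tables, a
16-dose (96-h) course with the trough at the next dose time gives
90.6%/88.1% exact. Analytic steady state with the trough at the infusion
start — the textbook convention — agrees with only ~53% of adult cells and
shifts the reference adult cell from 1.8 to 2.0 g/day, so the finite-course
conventions are the defaults; both are plain fields of `DoseSearchSpec`.
The under-4 grid maps PMA to postnatal age as (PMA − 40)/52.18 weeks.

The adult grid follows the printed table layout (4 ages × 6 weights × 5
creatinine × 4 BUN = 480 scenarios; open-ended ">2.5"/">40" columns are
evaluated at their boundary values). The source text counts 384 adult
scenarios (4 creatinine levels), which its own table contradicts; the
table wins here since agreement is assessed against it. Pediatric counts
(320 and 336) are consistent between text and tables and are reproduced.

Comorbidity adjustments multiply a base (male, comorbidity-free) dose by
0.77 / 0.85 / 0.80 for renal disease / diabetes / female — the published
rounded magnitudes of the clearance coefficients. The renal coefficient
0.237 strictly implies 23.7%; 23% is kept because it is the published
dosing instruction, and the 0.7-point rounding discrepancy is asserted in
the tests rather than hidden.

## Synthetic-data generator

`PopulationSpec` reproduces the study's marginal covariate structure:
~7.4% pediatric subjects (55% of them under 4), adult age truncated-normal
(median ≈60 y, range to 93), weight from a piecewise growth curve under
20 y and log-normal around 61 kg for adults, creatinine and BUN log-normal
around the published medians (0.7 / 15.25 mg/dL) with rank correlation 0.5
via a Gaussian copula and age-scaled creatinine for children. Comorbidity
prevalences are not published; defaults (diabetes 20%, renal disease 15%,
pneumonia 30%) are configurable assumptions. Dosing follows a label-style
policy (≈15 mg/kg rounded to 250 mg within 500–1500 mg, intervals 6–24 h,
3–5 days), with trough/peak pairs drawn on one or two late occasions
(three samples per subject on average, ≈1,600 observations for the
542-subject cohort vs the study's 1,526). The CRP subset (128 subjects,
samples every 2.5–3.5 days over 12–21-day stays, ≈830 observations vs 845)
draws random effects on k_D and CRP0 and applies 54.9% proportional error.

Per-subject RNG substreams derive deterministically from the global seed,
so subject i is identical regardless of cohort size and all outputs are
byte-reproducible. The generator emulates marginal distributions and the
sparse sampling design, not real-world features such as dose titration by
clinicians, within-subject creatinine drift, assay censoring below the
4 mg/L quantitation limit, or informative sampling — passing recovery
tests therefore demonstrates estimator correctness under the model, not
robustness to those violations.

## Estimation

The marginal likelihood over (η_CL, η_V2) is approximated per subject by
averaging the conditional likelihood over a fixed panel of standard-normal
draws (default 100, first draw pinned at the mode), scaled by the omegas.
Common draws across parameter values make the objective smooth and
deterministic, and the approximation collapses to the exact fixed-effect
−2 log-likelihood when both omegas are zero. Optimization is Nelder–Mead
on log-transformed structural parameters (relative tolerance 1e−6);
variance components and the weakly identified structural constants (PMA50,
γ, k_tox, k_Cr) stay fixed at their published values during recovery, as
the sparse adult-heavy design cannot inform them. Stepwise covariate
selection enters the largest ΔOFV first (forward ≥6.63, backward retention
≥10.82 for the PK thresholds), making the result independent of candidate
ordering. The VPC simulates replicate datasets at the observed design
points and summarizes the 2.5/50/97.5th percentiles per sample-type ×
time-tertile bin against their simulation confidence bands.

Note that with prediction-proportional residual variance the ML optimum on
noise-free data is not exactly the generating value (the log-variance term
rewards smaller predictions); exact-identifiability checks therefore use
additive-only error, while recovery under the full error model is assessed
statistically (clearance and volume within a few percent at 300 subjects,
tolerance ±15%).

Problem sizes in the test suite (cohorts of 80–300 subjects, 2 recovery
seeds, 24–100 likelihood draws) and the acceptance script (10 seeds × 300
subjects) were chosen as the smallest designs at which the Monte-Carlo
checks are stable.

## Known limitations

- The dose-optimizer trough conventions are reverse-engineered from the
  published tables; residual cell mismatches concentrate at extreme
  covariate corners and are quantified, not hidden, in the tests.
- The PD model inherits the source's simplifications: linear CRP–severity
  link, no bacterial-load mechanism, no PCT/ANC biomarkers, and no
  published D(0) or exposure-origin convention.
- The estimator is a desk-scale approximation (Monte-Carlo marginal
  likelihood, two random effects), not a FOCE-I replication; standard
  errors beyond a finite-difference Hessian are out of scope.
- Real-data diagnostics (goodness-of-fit to the hospital cohort) are not
  reproducible because that dataset is available only on request.
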