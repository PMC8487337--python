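# Methods

This note documents the models implemented in `ctpta`, the provenance and
calibration of the shipped default parameters, what the synthetic generators
do and do not emulate, and the numerical conventions used throughout.

## Plasma PK model

Disposition is a linear two-compartment model with first-order elimination,
parameterized by clearance CL (L/h), central volume V1 (L), distributional
clearance Q (L/h) and peripheral volume V2 (L). Dosing is a repeated
zero-order infusion (dose D over T_inf hours, every τ hours; default 1 h
every 8 h). The micro-constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2 give
macro-exponents α, β as roots of λ² − (k10+k12+k21)λ + k10·k21 = 0 with
coefficients A = (k21−α)/(V1(β−α)), B = (k21−β)/(V1(α−β)). Q = 0 collapses
to one compartment (λ = k10, coefficient 1/V1).

The steady-state profile over one interval is evaluated in closed form by
superposition: each exponential term carries the accumulation factor
1/(1 − e^(−λτ)) summing the tails of all previous doses, with separate
within-infusion and washout expressions joined at T_inf. The closed form is
cross-checked in the test suite against adaptive ODE integration run to
periodicity (agreement ≤ 1e-6 relative on random parameter draws), and obeys
the linear-PK identities AUC₀–τ,ss = D/CL and C(0) = C(τ).

Steady state is assumed throughout: the regimen is given for 8–14 days and
accumulation half-lives are a few hours at most, so all exposure and
target-attainment quantities are computed at periodic equilibrium.

## ELF link model

The pulmonary epithelial-lining-fluid (ELF) concentration follows a
hypothetical link compartment driven by plasma:
dC_E/dt = k_in·C_p(t) − k_out·C_E(t). Because C_p is piecewise
(constant + exponentials), the periodic ELF solution is closed form: particular
solutions per segment plus homogeneous e^(−k_out·t) terms fixed by continuity
at end of infusion and periodicity. The resonant case k_out = λ_i is handled
exactly with t·e^(−λt) terms. At steady state AUC_ELF/AUC_plasma = k_in/k_out
identically, which anchors the calibration of the rate-constant ratio.

The link is driven by **total** plasma concentration by default. The
published description does not state whether influx acts on total or free
plasma drug; both are implemented (`driven_by="total" | "free"`), and total
was chosen as the default because the binding correction is described as
applied at the target-evaluation step (ELF binding is 0 %, plasma binding 21 %
ceftolozane / 30 % tazobactam). With free driving, the ELF input simply
scales by fu_plasma.

## Default parameter sets and their calibration

The published analysis used proprietary population-PK parameter estimates
that are not printed in the trial report; only the model *structure*,
covariate relationships, binding fractions and summary exposures are public.
The shipped defaults in `src/ctpta/data/*.yaml` were therefore **calibrated**
so that the typical pneumonia patient at the reference covariates
(CrCl 110 mL/min, weight 80 kg) reproduces the published steady-state
geometric-mean exposures for the CrCl 80–150 mL/min bin exactly:

| anchor | ceftolozane | tazobactam |
|---|---|---|
| plasma AUC₀–₈ (μg·h/mL) | 371 | 61.9 |
| plasma Cmax (μg/mL) | 103 | 25.8 |
| ELF AUC₀–₈ (μg·h/mL) | 199 | 24.7 |
| ELF Cmax (μg/mL) | 28.3 | 4.68 |

Concretely: CL = dose/AUC; V1 solved so the typical Cmax matches with
plausible fixed Q and V2; k_in/k_out fixed at the ELF/plasma AUC ratio and
k_out solved so the typical ELF Cmax matches. The CrCl exponent on CL (0.79
ceftolozane, 0.75 tazobactam) reproduces the published decline of AUC across
CrCl bins. These defaults support reproducible simulation of the *behavior*
of the published analysis; they are not, and do not claim to be, the
proprietary estimates.

Between-subject variability magnitudes are nowhere printed in the report.
The published exposure %CVs (55–80 % geometric) conflate true
between-subject variability with residual and occasion noise; treating them
as pure IIV on clearance is inconsistent with the published attainment
profile (>99 % ceftolozane, >80 % tazobactam in every stratum) under any
parameterization anchored to the printed exposures. The defaults therefore
use moderate IIV — ω_CL 0.12 (ceftolozane) / 0.25 (tazobactam), ω_V 0.15,
ω_Q = ω_V2 0.15, ω_kin = ω_kout 0.20 (log-scale SDs) — chosen during
calibration so the simulated attainment profile matches the published
qualitative result: ceftolozane PTA above 0.99 everywhere, tazobactam above
0.80 with a monotone decline across the three ARC strata. Simulated exposure
geometric means match the anchors; simulated %CVs are consequently smaller
than the printed ones.

Pneumonia multipliers (1.22 on volumes, 1.25 on k_in, 1.10 on k_out) express
the covariate structure qualitatively (larger distribution volume and faster
pulmonary exchange with inflammation); the YAML `pk` block stores
non-pneumonia typical values such that with pneumonia applied — every
simulated patient has pneumonia — the anchors above are hit.

## Virtual population

Weight is log-normal (median 80 kg, log-SD 0.165, matching the published
IQR of roughly 72–90 kg). CrCl given weight is log-normal with
ln CrCl = ln 105 + 0.6·(ln WT − ln 80) + ε, ε ~ N(0, 0.35²), preserving the
positive weight–CrCl association; within a stratum the conditional
distribution is truncated to the stratum bounds, so every generated subject
lies inside its stratum by construction. With zero residual SD, CrCl is
deterministic in weight and weights are rejection-sampled.

Stratum boundary convention: intervals are closed on the left and open on
the right, except normal function [80, 130] (closed both ends, since 130 is
described as normal) and the terminal ARC cap [210, 312] (inclusive).
Two binnings coexist in the source material and both are implemented:
`canonical_strata()` (80–130, >130–<180, 180–<210, 210–312) for PTA and
`table_strata()` (≥80–<150, ≥150–<180, ≥180–<210, ≥210) for exposure
summaries. Neither is asserted to be "the" scheme of the published figures.

## PTA computation

Per subject, one steady-state profile per drug is computed on a 0.005-h grid
over [0, τ] with an exact node at end of infusion (Cmax occurs there for
this model class). fT>threshold is the Lebesgue measure of
{t : C_free(t) > threshold}, with sub-grid linear interpolation of crossing
times rather than naive grid counting; against a 10× denser grid the error
is well under 0.5 percentage points. Attainment uses ≥ at the boundary (a
subject exactly at 50 % attains — the target is "met"). PTA is the attained
fraction of the cohort, evaluated across doubling-dilution threshold grids
(0.125–64 μg/mL for MIC, 0.125–16 for C_T); the 90 % line in plots is an
annotation, not a decision rule.

Geometric exposure summaries use gm = exp(mean ln x) and
g%CV = 100·√(exp(s²_ln) − 1) with the n−1 sample variance; a single value
reports dispersion 0 by convention.

## Outcome statistics

Cockcroft–Gault with actual body weight: CrCl = (140 − age)·WT/(72·SCr),
×0.85 for females. Categories: [80, 130] normal, >130 ARC, <80 excluded
from the subgroup comparisons. Wilson score intervals use
z = Φ⁻¹(0.975) = 1.959964 (not 1.96) so CI endpoints reproduce published
1-dp values; Newcombe method 10 combines them around the point difference.
Display rounding is half-away-from-zero at 1 decimal (0.1511 pp prints as
0.2), with unrounded values retained on every object.

The published report states difference conventions ("normal minus ARC" for
mortality, "ARC minus normal" for cure) that are inconsistent with its own
printed signs. The comparison builder therefore takes the direction as an
explicit argument, and each packaged fixture row records the direction that
reproduces its printed numbers (mortality: ARC − normal; cure and
microbiologic cure: normal − ARC).

Counts not printed as n/N are recovered by exact inversion of the printed
1-dp percentage against the printed group size (`recover_count`); the
inversion is unique for every shipped row, is re-verified at load time, and
the rows are tagged `recovered` rather than presented as printed data.

**Known discrepancy.** The published clinical-cure C/T 95 % CI lower bound
(−14.8) cannot be produced by Newcombe method 10 from any counts consistent
with the published rates and group sizes (the method gives −14.747 → −14.7
at display rounding); a continuity-corrected variant would move other,
otherwise exactly matching, endpoints. The fixture stores both the published
and the method values, and the golden tests pin this single endpoint as the
only divergence among the 18 published numbers.

## Synthetic cohorts

`generate_cohort` draws age (normal, truncated at 18), sex, weight and
sex-specific serum creatinine (log-normal, median 1.0/0.85 mg/dL, log-SD
0.45), derives CrCl through Cockcroft–Gault — so renal categories emerge
mechanistically, about 36 % normal / 26 % ARC / 38 % other, echoing the
trial's 35 %/29 % split — and draws binary outcomes Bernoulli at
category-specific rates (defaults set to the published subgroup rates). The
generator does **not** simulate treatment effects, correlations between
endpoints, time-to-event structure, or post-baseline renal drift; passing
tests demonstrate that the statistical pipeline recovers known inputs, not
that real trial data behave this way.

A single seed is expanded into named substreams (demographics, IIV per
stratum × drug, outcomes) via seed sequences, so enlarging one stage never
perturbs another and golden outputs are stable.

## Problem sizes and determinism

Default study sizes follow the published design: 1000 virtual patients per
renal stratum for PTA, with exposure summaries at 1000 per bin and
synthetic-recovery checks at 10,000 per arm. The full stratified PTA study
runs in seconds on one CPU. All randomness flows from explicit integer
seeds; repeated runs with the same seed are bit-identical, and Monte Carlo
spread at n = 1000 keeps PTA reproducible to within a few percentage points
across seeds.

## Known limitations

- Binding is linear (fixed unbound fractions); no saturable elimination.
- The ELF link is phenomenological; it reproduces penetration ratios, not
  lung physiology.
- Default parameters are calibrated to printed summary exposures, not
  estimated from concentration data; inferences about the proprietary model
  beyond its published behavior are out of scope.
- The comparator arm (meropenem) has no PK model here — the trial collected
  no meropenem PK — so only its outcome statistics are represented.
- mITT and CE subgroup denominators for mortality/clinical cure are not
  published; those comparisons are reproducible in structure only.
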