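# ctpta

Population-PK Monte Carlo simulation of **probability of target attainment
(PTA)** for ceftolozane/tazobactam in nosocomial pneumonia, plus the
renal-subgroup **outcome statistics** (Newcombe confidence intervals on
proportion differences) used to compare clinical results between patients
with normal renal function and augmented renal clearance (ARC).

## The problem

Critically ill patients with hospital-acquired or ventilator-associated
bacterial pneumonia (HABP/VABP) frequently exhibit ARC — creatinine clearance
(CrCl) above 130 mL/min — which accelerates elimination of renally cleared
β-lactams and can undermine efficacy. Two questions follow for a fixed
3 g ceftolozane/tazobactam dose (2 g/1 g as a 1-h infusion every 8 h):

1. **Pharmacometric**: across renal-function strata (CrCl 80–130 normal;
   >130–<180, 180–<210, 210–312 mL/min ARC), what fraction of patients attain
   the PK/PD targets — 50 % *f*T>MIC at MIC 4 μg/mL for ceftolozane and
   35 % *f*T>C_T at C_T 1 μg/mL for tazobactam — in plasma and in pulmonary
   epithelial lining fluid (ELF)?
2. **Clinical**: are 28-day all-cause mortality, clinical cure and
   microbiologic cure comparable between normal-renal-function and ARC
   subgroups within each treatment arm?

## The model

Plasma follows a two-compartment model with zero-order infusion and
first-order elimination. At periodic steady state the concentration over one
dosing interval τ is the closed-form superposition of biexponential
infusion/post-infusion segments with accumulation factors 1/(1 − e^(−λτ)).
ELF is a hypothetical link compartment,

    dC_ELF/dt = k_in · C_plasma(t) − k_out · C_ELF(t),

whose periodic solution is likewise closed form; at steady state
AUC_ELF/AUC_plasma = k_in/k_out. Free concentrations use fixed unbound
fractions (ceftolozane 0.79 plasma / 1.0 ELF; tazobactam 0.70 / 1.0).
Covariates enter as power laws — CL ∝ (CrCl/CrCl_ref)^θ, V ∝ (WT/WT_ref)^θ
with pneumonia multipliers on volume and on k_in/k_out — with log-normal
between-subject variability. Virtual patients carry paired weight and CrCl
drawn from a conditional log-normal model truncated to each stratum.

For the outcome comparisons, CrCl is the sex-specific Cockcroft–Gault
estimate with actual body weight, and two-group differences use the Newcombe
method-10 interval built from Wilson score intervals (l_i, u_i):

    d ∈ [d − √((p₁−l₁)² + (u₂−p₂)²),  d + √((u₁−p₁)² + (p₂−l₂)²)]

## Worked example

```python
import numpy as np
from ctpta import load_drug_spec, newcombe_diff_ci
from ctpta.study import run_pta_study

# published microbiologic cure counts, normal renal function minus ARC
c = newcombe_diff_ci(66, 88, 49, 70, label="micro cure, meropenem")
print(c.display)                # (5.0, -8.7, 19.0)  -> 5.0 pp [−8.7, 19.0]

specs = [load_drug_spec("ceftolozane"), load_drug_spec("tazobactam")]
grids = {"ceftolozane": np.array([4.0]), "tazobactam": np.array([1.0])}
frame, _ = run_pta_study(specs, n_per_stratum=1000, seed=1, grids=grids)
print(frame[(frame.drug == "tazobactam") & (frame.matrix == "plasma")]
      [["stratum", "pta"]].to_string(index=False))
```

The first line reproduces the published meropenem microbiologic-cure
comparison: a 5.0-percentage-point difference with 95 % CI −8.7 to 19.0.
The simulation block prints tazobactam plasma PTA at C_T 1 μg/mL by stratum:

```
stratum   pta
 80-130 1.000
130-180 0.995
180-210 0.980
210-312 0.941
```

PTA stays above 0.80 everywhere but declines monotonically with increasing
ARC severity, while ceftolozane PTA (not shown) exceeds 0.99 in every stratum
and matrix — the qualitative profile expected for this regimen.

A CLI wraps the same functions:

```bash
ctpta simulate-pta --n-per-stratum 1000 --seed 1 --out pta.csv --plot pta.png
ctpta compare-outcomes --out comparisons.csv
ctpta summarize-exposure --seed 1 --out exposures.csv
ctpta generate-cohort --n-per-arm 250 --seed 1 --out cohort.csv
```

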