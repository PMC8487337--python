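# Ceftolozane parameter set (calibrated package defaults).
#
# Units: dose mg; durations/intervals h; CL, Q L/h; V1, V2 L; k_in, k_out 1/h;
# unbound fractions dimensionless; CrCl mL/min; weight kg; omegas are log-scale SDs.
#
# The pk block is the typical subject WITHOUT pneumonia at the reference
# covariates (CrCl 110 mL/min, weight 80 kg).  With the pneumonia multipliers
# applied (every simulated patient has pneumonia), the typical steady-state
# exposures for 2000 mg infused over 1 h every 8 h are:
#   plasma AUC0-8 371 ug*h/mL, plasma Cmax 103 ug/mL,
#   ELF AUC0-8 199 ug*h/mL,    ELF Cmax 28.3 ug/mL,
# the geometric-mean anchors used to calibrate this file.
drug: ceftolozane
regimen:
  dose_mg: 2000.0
  infusion_h: 1.0
  interval_h: 8.0
pk:
  cl: 5.3908
  v1: 15.3877
  q: 1.5
  v2: 3.6885
  k_in: 0.08424
  k_out: 0.178455
  fu_plasma: 0.79   # 21% plasma protein binding
  fu_elf: 1.0       # no binding in ELF
covariates:
  cl_ref: 5.3908
  cl_crcl_exponent: 0.79
  crcl_ref: 110.0
  v_ref: 15.3877
  v_weight_exponent: 0.75
  wt_ref: 80.0
  pneumonia_v_multiplier: 1.22
  pneumonia_kin_multiplier: 1.25
  pneumonia_kout_multiplier: 1.10
iiv:
  omega_cl: 0.12
  omega_v1: 0.15
  omega_q: 0.15
  omega_v2: 0.15
  omega_kin: 0.20
  omega_kout: 0.20
target:
  threshold_type: MIC
  threshold_value: 4.0
  required_fraction: 0.50
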