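# Tazobactam parameter set (calibrated package defaults).
#
# Units as in ceftolozane.yaml.  The pk block is the typical subject WITHOUT
# pneumonia at the reference covariates (CrCl 110 mL/min, weight 80 kg).
# With pneumonia multipliers applied, the typical steady-state exposures for
# 1000 mg infused over 1 h every 8 h are:
#   plasma AUC0-8 61.9 ug*h/mL, plasma Cmax 25.8 ug/mL,
#   ELF AUC0-8 24.7 ug*h/mL,    ELF Cmax 4.68 ug/mL,
# the geometric-mean anchors used to calibrate this file.
drug: tazobactam
regimen:
  dose_mg: 1000.0
  infusion_h: 1.0
  interval_h: 8.0
pk:
  cl: 16.1551
  v1: 23.8574
  q: 4.0
  v2: 4.0984
  k_in: 0.135920
  k_out: 0.387000
  fu_plasma: 0.70   # 30% plasma protein binding
  fu_elf: 1.0       # no binding in ELF
covariates:
  cl_ref: 16.1551
  cl_crcl_exponent: 0.75
  crcl_ref: 110.0
  v_ref: 23.8574
  v_weight_exponent: 0.75
  wt_ref: 80.0
  pneumonia_v_multiplier: 1.22
  pneumonia_kin_multiplier: 1.25
  pneumonia_kout_multiplier: 1.10
iiv:
  omega_cl: 0.25
  omega_v1: 0.15
  omega_q: 0.15
  omega_v2: 0.15
  omega_kin: 0.20
  omega_kout: 0.20
target:
  threshold_type: C_T
  threshold_value: 1.0
  required_fraction: 0.35
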