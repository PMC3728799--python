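# Demo run configuration: synthetic adult physiology + the fast/medium/slow
# oral triplet (100 mg Weibull release models) and an IV reference dose.
# Every key embeds its unit; the physiology block must list exactly the 22
# model parameters (unknown or missing keys are rejected).
physiology:
  V_gics_L: 1.2
  V_liver_L: 1.8
  V_plasma_L: 12.0
  V_tissues_L: 30.0
  V_lumen_stomach_L: 0.25
  V_lumen_si_L: 0.6
  V_lumen_li_L: 0.3
  Q_gics_L_per_h: 60.0
  Q_portal_L_per_h: 60.0
  Q_hepatic_out_L_per_h: 60.0
  Q_tissues_L_per_h: 20.0
  k_gastric_per_h: 2.8
  k_si_transit_per_h: 0.35
  k_li_transit_per_h: 0.05
  PA_stomach_L_per_h: 0.05
  PA_si_L_per_h: 4.0
  PA_li_L_per_h: 0.3
  CL_hepatic_L_per_h: 40.0
  CL_renal_L_per_h: 2.0
  F_unbound_factor: 8.0
  t_form_gastric_h: 2.0
  t_form_si_h: 3.0
doses:
  fast:
    route: oral
    amount_mg: 100.0
    release:
      form: weibull
      M_inf_mg: 100.0
      tau_h: 1.5
      beta: 1.4
  medium:
    route: oral
    amount_mg: 100.0
    release:
      form: weibull
      M_inf_mg: 100.0
      tau_h: 3.0
      beta: 1.4
  slow:
    route: oral
    amount_mg: 100.0
    release:
      form: weibull
      M_inf_mg: 100.0
      tau_h: 6.0
      beta: 1.4
  iv_reference:
    route: iv_bolus
    amount_mg: 25.0
free_parameters:
- PA_si
- CL_hepatic
- Q_tissues
- F_unbound_factor
seed: 1
output_dir: results
log_level: INFO
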