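# Default configuration for igpbpk.
#
# Provenance tags: {published} published reference value; {derived}
# back-calculated from published summaries; {calibrated} fixed once by
# scripts/calibrate_baselines.py; {placeholder} configurable stand-in with
# no published source.

physiology:
  reference_bodyweight: 70.0   # kg {published}
  plasma_volume: 2.6           # L, nonpregnant 70-kg adult {published}
  tight_volume: 8.11           # L {published}
  leaky_volume: 4.37           # L {published}
  lymph_volume: 5.2            # L {published}
  lymph_flow_total: 2.9        # L/day {published}
  sigma_lymph: 0.2             # lymphatic capillary reflection coefficient {published}
  leaky_flow_fraction: 0.6666666666666666  # share of lymph flow to leaky tissue {derived: two-tissue mPBPK convention}

pregnancy:
  trimester_plasma_volume:     # L at 70 kg: +7% / +27% / +41% by trimester {published}
    0: 2.6
    1: 2.78
    2: 3.30
    3: 3.67
  pregnancy_bw_gain: 0.23      # third-trimester bodyweight gain fraction {published}
  baseline_igg:                # endogenous plasma IgG, g/L {calibrated}
    0: 13.0
    1: 12.98
    2: 12.95
    3: 12.93

drugs:
  ivig:
    clearance: 0.045           # L/day at 70 kg {published}
    sigma_tight: 0.97          # vascular reflection coefficient, tight tissue {published}
    sigma_leaky: 0.94          # vascular reflection coefficient, leaky tissue {published}
    ka: null                   # IV product: no absorption phase
    bioavailability_im: 1.0    # unused for IV {placeholder}
    infusion_duration: 0.16666666666666666  # day (4 h) {placeholder}
  anti_d:
    clearance: 0.045           # L/day at 70 kg {placeholder: IgG-like}
    sigma_tight: 0.97          # {placeholder: IgG-like}
    sigma_leaky: 0.94          # {placeholder: IgG-like}
    ka: 0.25                   # 1/day, IM first-order absorption {placeholder}
    bioavailability_im: 1.0    # {placeholder}
    infusion_duration: 0.020833333333333332  # day (30 min) {placeholder}

population:
  n: 100                       # virtual subjects per arm {published}
  bw_mean: 74.0                # kg {derived: total dose 37 g at 0.5 g/kg}
  bw_sd: 18.0                  # kg {derived: total dose SD 9 g at 0.5 g/kg}
  gain_fraction: 0.23          # {published}
  dose_per_kg: 0.5             # g/kg {published}
  trough_time: 28.0            # day {calibrated: standard 4-week dosing interval}
  trimester: 3                 # {published}
  seed: 20317                  # default cohort seed {placeholder}
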