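# Base-case decision problem: sacituzumab tirumotecan (sac-TMT) vs
# platinum-based chemotherapy, second line, EGFR-mutant advanced NSCLC,
# Chinese healthcare system perspective, 2025 USD.
#
# Calibration knobs committed with the base case (see docs/methods.md):
#   vial_policy: exact        — administered milligrams priced linearly
#   followup_schedule.mri_every_n_cycles: 0 — MRI not in the routine bundle
#   pd_mix: 100% best supportive care in both arms
name: sac-tmt-vs-chemo-basecase
engine: both
cycle_days: 28
horizon_years: 10.0
discount_annual: 0.05
wtp_per_qaly: 41811.0
background_annual_mortality: 0.00804
vial_policy: exact
comparator: chemotherapy

patient:
  weight_kg: 65.0
  bsa_m2: 1.72
  crcl_ml_min: 70.0

utilities:
  pfs: {base: 0.804, low: 0.536, high: 0.840}
  pd: {base: 0.321, low: 0.031, high: 0.473}

drugs:
  sac_tmt:
    vial_strength_mg: 200.0
    unit_price: {base: 1315.85, low: 1052.68, high: 1579.02}
    dosing: {rule: per_kg, amount: 5.0}          # 5 mg/kg, days 1 and 15
  pemetrexed:
    vial_strength_mg: 500.0
    unit_price: {base: 65.52, low: 52.42, high: 78.62}
    dosing: {rule: per_bsa, amount: 500.0}       # 500 mg/m2
  carboplatin:
    vial_strength_mg: 150.0
    unit_price: {base: 11.06, low: 8.85, high: 13.27}
    dosing: {rule: auc, amount: 5.0}             # Calvert, AUC 5
  cisplatin:
    vial_strength_mg: 200.0
    unit_price: {base: 1.71, low: 1.37, high: 2.05}
    dosing: {rule: per_bsa, amount: 75.0}        # 75 mg/m2 (config alternative)
  osimertinib:
    vial_strength_mg: 80.0
    unit_price: {base: 23.18, low: 18.54, high: 27.81}
    dosing: {rule: flat, amount: 80.0}           # one 80 mg tablet daily

costs:
  bsc_per_cycle: {base: 436.19, low: 348.95, high: 523.43}
  followup:
    cbc:          {base: 2.10,  low: 1.68,  high: 2.52}
    biochemistry: {base: 25.20, low: 20.16, high: 30.24}
    urinalysis:   {base: 2.52,  low: 2.02,  high: 3.02}
    ct:           {base: 11.20, low: 8.96,  high: 13.44}
    mri:          {base: 70.00, low: 56.00, high: 84.00}
    nursing_day:  {base: 3.64,  low: 2.91,  high: 4.37}
    bed_day:      {base: 2.80,  low: 2.24,  high: 3.36}
    consultation: {base: 3.08,  low: 2.46,  high: 3.70}
    injection:    {base: 0.81,  low: 0.65,  high: 0.97}
    preparation:  {base: 4.76,  low: 3.81,  high: 5.71}

followup_schedule:
  consultations_per_cycle: 1
  cbc_per_cycle: 1
  biochemistry_per_cycle: 1
  urinalysis_per_cycle: 1
  ct_every_n_cycles: 2
  mri_every_n_cycles: 0
  include_in_pd: true

adverse_events:
  - name: anemia
    cost: {base: 448.56, low: 358.85, high: 538.27}
    disutility: {base: -0.073, low: -0.088, high: -0.058}
    incidence:
      sac_tmt:      {base: 0.110, low: 0.088, high: 0.132}
      chemotherapy: {base: 0.140, low: 0.112, high: 0.168}
  - name: leukopenia
    cost: {base: 421.40, low: 337.12, high: 505.68}
    disutility: {base: -0.200, low: -0.240, high: -0.160}
    incidence:
      sac_tmt:      {base: 0.280, low: 0.224, high: 0.336}
      chemotherapy: {base: 0.220, low: 0.176, high: 0.264}
  - name: neutropenia
    cost: {base: 406.56, low: 325.25, high: 487.87}
    disutility: {base: -0.200, low: -0.240, high: -0.160}
    incidence:
      sac_tmt:      {base: 0.400, low: 0.320, high: 0.480}
      chemotherapy: {base: 0.330, low: 0.264, high: 0.396}
  - name: thrombocytopenia
    cost: {base: 2937.46, low: 2349.97, high: 3524.95}
    disutility: {base: -0.190, low: -0.228, high: -0.152}
    incidence:
      sac_tmt:      {base: 0.020, low: 0.016, high: 0.024}
      chemotherapy: {base: 0.160, low: 0.128, high: 0.192}

strategies:
  sac_tmt:
    label: "sac-TMT"
    curves:
      pfs: {family: lognormal,   params: [2.20, 0.999]}
      os:  {family: loglogistic, params: [1.538, 27.354]}
    treatment:
      kind: fixed_cycle
      components:
        - {drug: sac_tmt, administrations_per_cycle: 2}
    pd_mix: {bsc: 1.0}
  chemotherapy:
    label: "Chemotherapy"
    curves:
      pfs: {family: loglogistic, params: [2.420, 4.590]}
      os:  {family: weibull_ph,  params: [1.599, 0.007]}
    treatment:
      kind: induction_maintenance
      regimen_cycle_days: 21
      induction_regimen_cycles: 4
      induction:
        - {drug: pemetrexed,  administrations_per_cycle: 1}
        - {drug: carboplatin, administrations_per_cycle: 1}
      maintenance:
        - {drug: pemetrexed, administrations_per_cycle: 1}
    pd_mix: {bsc: 1.0}

psa:
  iterations: 1000
  seed: 20260926

scenarios:
  - name: nrdl_price
    overrides: {"price.sac_tmt": 637.0}
    wtp_thresholds: [41811.0]
  - name: gdp_multiples
    overrides: {}
    wtp_thresholds: [13937.0, 27874.0, 41811.0]
  - name: regional_wtp
    overrides: {}
    wtp_thresholds: [59532.0, 70155.0, 96180.0, 100380.0]
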