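settings:
  cycle_days: 21.0
  horizon_cycles: 174
  discount_rate: 0.05
  wtp: 38224.0
  background_mortality_annual: 0.002
  half_cycle_correction: false
patient:
  bsa_m2: 1.72
  weight_kg: 65.0
costs:
  drug_prices_per_100mg:
    pembrolizumab: 2451.6
    gemcitabine: 18.64
    carboplatin: 7.06
    nab_paclitaxel: 20.25
    paclitaxel: 24.75
  supportive:
    amount: 359.0
    state: pfs
    max_cycles: 6
  followup:
    amount: 170.0
    state: pd
  terminal_care: 2325.75
  ae_event_costs:
    anemia: 607.06
    neutropenia: 547.5
    neutrophil_count_decreased: 104.95
utilities:
  pfs: 0.76
  pd: 0.55
  ae_disutilities:
    anemia: 0.029
    neutropenia: 0.012
    neutrophil_count_decreased: 0.2
intervention:
  name: pembrolizumab_chemotherapy
  pfs_curve:
    family: lognormal
    params:
    - 2.3487
    - 1.2258
  os_curve:
    family: lognormal
    params:
    - 3.1454
    - 1.1058
  regimen:
  - name: pembrolizumab
    dose_rule: flat
    dose_mg: 200.0
    admins_per_cycle: 1
    weight: 1.0
    max_cycles: 35
  - name: gemcitabine
    dose_rule: per_m2
    dose_mg: 1000.0
    admins_per_cycle: 2
    weight: 0.55
    max_cycles: 6
  - name: carboplatin
    dose_rule: flat
    dose_mg: 625.0
    admins_per_cycle: 1
    weight: 0.55
    max_cycles: 6
  - name: nab_paclitaxel
    dose_rule: per_m2
    dose_mg: 100.0
    admins_per_cycle: 3
    weight: 0.31
    max_cycles: 6
  - name: paclitaxel
    dose_rule: per_m2
    dose_mg: 90.0
    admins_per_cycle: 3
    weight: 0.14
    max_cycles: 6
  ae_incidence:
    anemia: 0.165
    neutropenia: 0.297
    neutrophil_count_decreased: 0.174
comparator:
  name: placebo_chemotherapy
  pfs_curve:
    family: loglogistic
    params:
    - 1.763
    - 6.618
  os_curve:
    family: loglogistic
    params:
    - 1.702
    - 16.631
  regimen:
  - name: gemcitabine
    dose_rule: per_m2
    dose_mg: 1000.0
    admins_per_cycle: 2
    weight: 0.55
    max_cycles: 6
  - name: carboplatin
    dose_rule: flat
    dose_mg: 625.0
    admins_per_cycle: 1
    weight: 0.55
    max_cycles: 6
  - name: nab_paclitaxel
    dose_rule: per_m2
    dose_mg: 100.0
    admins_per_cycle: 3
    weight: 0.31
    max_cycles: 6
  - name: paclitaxel
    dose_rule: per_m2
    dose_mg: 90.0
    admins_per_cycle: 3
    weight: 0.14
    max_cycles: 6
  ae_incidence:
    anemia: 0.146
    neutropenia: 0.299
    neutrophil_count_decreased: 0.203
psa:
  n_iterations: 1000
  seed: 12345
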