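chart_format: svg
charts: true
discovery:
  exclusions: []
  threshold: 1000
  threshold_year: 2020
  topic_rules:
  - codes: []
    keywords:
    - medication
    - review
    name: medication
    prefixes: []
  - codes: []
    keywords:
    - screening
    - smear
    name: screening
    prefixes: []
  - codes: []
    keywords:
    - blood pressure
    - cardiovascular
    name: cardiovascular
    prefixes: []
disruption:
  disruption_month: 2020-04
  drop_fraction: 0.6
  recovery_months: 8
  recovery_shape: linear
  terminal_level: 1.0
disruption_prefix: null
disruption_start: 2020-04
groups: []
key_months:
- 2020-02
- 2020-04
- 2020-12
max_chart_subjects: 4
quantile_rule: linear
recovery_thresholds:
  increase_terminal: 10.0
  maintained_drop: -20.0
  partial_lower: -30.0
  recovered_lower: -10.0
synthetic:
  attrition_fraction_start: 0.07
  base_rate_meanlog: 0.6931471805599453
  base_rate_sdlog: 1.5
  dispersion: 0.15
  index_date: '2020-12-31'
  keywords:
  - review
  - screening
  - monitoring
  - examination
  - smear
  - medication
  list_size_meanlog: 8.987196820661973
  list_size_sdlog: 0.5
  n_codes: 40
  n_practices: 150
  practice_effect_sd: 0.35
  seasonality_amplitude: 0.1
  seasonality_peak_month: 1
  seed: 2020
  study_end: 2020-12
  study_start: 2019-01
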