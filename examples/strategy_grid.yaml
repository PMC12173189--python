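# Strategy-comparison grid: four age ranges x three screening intervals,
# imperfect attendance, moderate size-sensitivity, study-size population.
seed: 20260921
cohort: {births_per_cohort: 5000, n_cohorts: 35}
scenarios:
  - {name: early_annual,    policy: {start_age: 30, end_age: 65, interval: 1}, attendance: imperfect, sensitivity: moderate}
  - {name: early_biennial,  policy: {start_age: 30, end_age: 65, interval: 2}, attendance: imperfect, sensitivity: moderate}
  - {name: early_triennial, policy: {start_age: 30, end_age: 65, interval: 3}, attendance: imperfect, sensitivity: moderate}
  - {name: sweden_annual,    policy: {start_age: 40, end_age: 74, interval: 1}, attendance: imperfect, sensitivity: moderate}
  - {name: sweden_biennial,  policy: {start_age: 40, end_age: 74, interval: 2}, attendance: imperfect, sensitivity: moderate}
  - {name: sweden_triennial, policy: {start_age: 40, end_age: 74, interval: 3}, attendance: imperfect, sensitivity: moderate}
  - {name: iarc_annual,    policy: {start_age: 50, end_age: 69, interval: 1}, attendance: imperfect, sensitivity: moderate}
  - {name: iarc_biennial,  policy: {start_age: 50, end_age: 69, interval: 2}, attendance: imperfect, sensitivity: moderate}
  - {name: iarc_triennial, policy: {start_age: 50, end_age: 69, interval: 3}, attendance: imperfect, sensitivity: moderate}
  - {name: iarc_ext_annual,    policy: {start_age: 50, end_age: 74, interval: 1}, attendance: imperfect, sensitivity: moderate}
  - {name: iarc_ext_biennial,  policy: {start_age: 50, end_age: 74, interval: 2}, attendance: imperfect, sensitivity: moderate}
  - {name: iarc_ext_triennial, policy: {start_age: 50, end_age: 74, interval: 3}, attendance: imperfect, sensitivity: moderate}
output_dir: strategy-grid-output
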