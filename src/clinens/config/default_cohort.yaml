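# Default synthetic cohort: 93 patients, 15 binary raters, 9 tasks in three
# modality groups, three correlation clusters, repeat queries on T4-T6.
# Rater profiles span an "aggressive" extreme (near-perfect sensitivity,
# near-zero specificity), a "conservative" extreme (high specificity, low
# sensitivity) and a mid-range majority, with modest gains on the
# history-augmented tasks (T4-T6 group columns are shared with the base
# tasks of the same modality here, since groups are modality triples).
n_patients: 93
prevalence: 0.681
age_mean: 66.63
age_sd: 9.30
age_range: [35.0, 83.0]
male_fraction: 0.677
cluster_correlation: 0.45
seed: 0
replicate_count: {T4: 3, T5: 3, T6: 3}
task_scheme:
  CAG: [T1, T4, T7]
  CTA: [T2, T5, T8]
  MULTI: [T3, T6, T9]
models:
  - model_name: rater-aggr-1
    cluster_id: alpha
    se_by_group: {CAG: 0.996, CTA: 0.99, MULTI: 0.99}
    sp_by_group: {CAG: 0.10, CTA: 0.05, MULTI: 0.05}
    replicate_flip: 0.03
  - model_name: rater-aggr-2
    cluster_id: alpha
    se_by_group: {CAG: 0.97, CTA: 0.95, MULTI: 0.96}
    sp_by_group: {CAG: 0.20, CTA: 0.15, MULTI: 0.12}
    replicate_flip: 0.05
  - model_name: rater-cons-1
    cluster_id: beta
    se_by_group: {CAG: 0.60, CTA: 0.55, MULTI: 0.58}
    sp_by_group: {CAG: 0.95, CTA: 0.93, MULTI: 0.94}
    replicate_flip: 0.04
  - model_name: rater-cons-2
    cluster_id: beta
    se_by_group: {CAG: 0.66, CTA: 0.62, MULTI: 0.64}
    sp_by_group: {CAG: 0.92, CTA: 0.90, MULTI: 0.91}
    replicate_flip: 0.06
  - model_name: rater-mid-01
    cluster_id: alpha
    se_by_group: {CAG: 0.90, CTA: 0.85, MULTI: 0.88}
    sp_by_group: {CAG: 0.55, CTA: 0.50, MULTI: 0.52}
    replicate_flip: 0.05
  - model_name: rater-mid-02
    cluster_id: alpha
    se_by_group: {CAG: 0.88, CTA: 0.84, MULTI: 0.86}
    sp_by_group: {CAG: 0.60, CTA: 0.55, MULTI: 0.58}
    replicate_flip: 0.05
  - model_name: rater-mid-03
    cluster_id: beta
    se_by_group: {CAG: 0.82, CTA: 0.78, MULTI: 0.80}
    sp_by_group: {CAG: 0.72, CTA: 0.68, MULTI: 0.70}
    replicate_flip: 0.05
  - model_name: rater-mid-04
    cluster_id: beta
    se_by_group: {CAG: 0.80, CTA: 0.76, MULTI: 0.78}
    sp_by_group: {CAG: 0.75, CTA: 0.70, MULTI: 0.72}
    replicate_flip: 0.06
  - model_name: rater-mid-05
    cluster_id: gamma
    se_by_group: {CAG: 0.86, CTA: 0.80, MULTI: 0.84}
    sp_by_group: {CAG: 0.66, CTA: 0.60, MULTI: 0.63}
    replicate_flip: 0.04
  - model_name: rater-mid-06
    cluster_id: gamma
    se_by_group: {CAG: 0.84, CTA: 0.79, MULTI: 0.82}
    sp_by_group: {CAG: 0.68, CTA: 0.62, MULTI: 0.65}
    replicate_flip: 0.05
  - model_name: rater-mid-07
    cluster_id: gamma
    se_by_group: {CAG: 0.78, CTA: 0.72, MULTI: 0.75}
    sp_by_group: {CAG: 0.78, CTA: 0.74, MULTI: 0.76}
    replicate_flip: 0.05
  - model_name: rater-mid-08
    cluster_id: gamma
    se_by_group: {CAG: 0.76, CTA: 0.70, MULTI: 0.73}
    sp_by_group: {CAG: 0.80, CTA: 0.76, MULTI: 0.78}
    replicate_flip: 0.06
  - model_name: rater-var-1
    cluster_id: alpha
    se_by_group: {CAG: 0.92, CTA: 0.70, MULTI: 0.85}
    sp_by_group: {CAG: 0.40, CTA: 0.65, MULTI: 0.50}
    replicate_flip: 0.10
  - model_name: rater-var-2
    cluster_id: beta
    se_by_group: {CAG: 0.70, CTA: 0.88, MULTI: 0.78}
    sp_by_group: {CAG: 0.82, CTA: 0.45, MULTI: 0.66}
    replicate_flip: 0.09
  - model_name: rater-var-3
    cluster_id: gamma
    se_by_group: {CAG: 0.74, CTA: 0.80, MULTI: 0.90}
    sp_by_group: {CAG: 0.76, CTA: 0.62, MULTI: 0.42}
    replicate_flip: 0.08
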