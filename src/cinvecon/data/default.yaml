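# Default analysis configuration: the published observed cohort data, beta
# priors from the literature, the laboratory price list (USD) and the
# sampler/scenario settings.  Per-reaction PCR prices are the single-test
# reagent ($8.56) and material ($1.07) lines divided by the 5 reactions of a
# one-sample run (1 sample + 4 controls); stage hours are 3h56m, 2h20m, 20m;
# the staff rate is $1,585.65 per 160-hour month.
credible_level: 0.95
output_dir: results

observations:
  p_high_risk: {events: 45, total: 88}
  p_cinv: {events: 4, total: 43}
  p_cycle2: {events: 86, total: 88}
  p_cycle3_given_cycle2: {events: 64, total: 86}

priors:
  p_high_risk: {alpha: 178, beta: 114}
  p_cinv: {alpha: 33, beta: 191}
  p_cycle2: {alpha: 160, beta: 12}
  p_cycle3_given_cycle2: {alpha: 120, beta: 40}

sampler:
  iterations: 12500
  burn_in: 2500
  seed: 2019
  proposal_scale: 0.5
  adapt: true

unit_costs:
  fosaprepitant_per_dose: 81.08
  dna_reagent_per_sample: 1.46
  pcr_reagent_per_reaction: 1.7120000000000002
  pcr_material_per_reaction: 0.21400000000000002
  controls_per_run: 4
  manpower_rate_per_hour: 9.9103125
  stage_hours_extraction: 3.9333333333333336
  stage_hours_pcr: 2.3333333333333335
  stage_hours_reporting: 0.3333333333333333
  machine_cost: 36364.86
  amortization_rate: 0.20
  initial_investment: 39379.97

scenario:
  n_patients: [300]
  batch_sizes: [2, 6]
  conventions: [intent_to_treat, dropout_adjusted]
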