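# Default end-to-end run configuration.  The cohorts are synthetic: the
# intervention arm emulates a single-arm anti-PD-1 trial in MSI-H/dMMR
# colorectal cancer (immature OS with a long-term-survivor plateau), the
# comparator a published regorafenib trial available only as digitized
# KM curves.  Paths are resolved against the packaged data directory
# unless absolute.
seed: 20230426

cohorts:
  intervention:
    arm: serplulimab
    n: 74                 # inferred scale of the CRC subset; configurable
    cure_fraction: 0.45
    latent_os_family: lognormal
    latent_os_params: [2.2, 0.8]      # median ~9 months among uncured
    pfs_family: weibull
    pfs_params: [8.0, 1.2]
    covariate_prevalences:
      age: 53.0
      male: 0.60
      ecog1: 0.70
      histology_adeno: 0.90
      liver_met: 0.45
      prior_lines_ge2: 0.55
      prior_targeted: 0.35
    accrual_months: 12.0
    followup_months: 36.0
    long_pfs_prob: 0.7
  comparator:
    arm: regorafenib
    n: 136                # regorafenib arm size of the comparator trial
    cure_fraction: 0.0
    latent_os_family: loglogistic
    latent_os_params: [8.8, 1.7]      # median OS ~8.8 months
    pfs_family: loglogistic
    pfs_params: [3.2, 1.9]            # median PFS ~3.2 months
    accrual_months: 12.0
    followup_months: 30.0

digitization:
  curve_max_months: 28.0
  curve_step_months: 0.5
  risk_table_step_months: 2.0

maic:
  enabled: true
  covariates: [age, male, ecog1, histology_adeno, liver_met, prior_lines_ge2, prior_targeted]
  targets_csv: maic_targets_synthetic.csv

survival:
  families:
    intervention_pfs: gompertz
    intervention_os_latent: lognormal   # mixture cure on OS
    comparator_pfs: loglogistic
    comparator_os: loglogistic
  start_age: 55.0        # required assumption; no fidelity claim
  male_prop: 0.60
  death_risk_multiplier: 2.0
  max_cycles: 800

economics: economic_inputs.yaml
life_table: life_table_synthetic.csv
published_summary: published_summary_results.csv

horizon: lifetime        # or an integer cycle count (36 months = 39 cycles)

uncertainty:
  owsa_variation: 0.20
  psa_draws: 1000
  lambda_max: 60000.0
  lambda_step: 500.0
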