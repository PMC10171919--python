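# Cost, utility and adverse-event inputs (2022 USD, converted at
# 6.7413 CNY per USD) transcribed from the published Chinese
# cost-effectiveness analysis of serplulimab vs regorafenib in
# previously treated MSI-H/dMMR colorectal cancer.
#
# Monetary values are carried verbatim at two-decimal (cent) precision.
# Notes on two transcriptions kept verbatim despite arithmetic tension
# with the stated unit prices:
#  * regorafenib acquisition/cycle 2149.19 (21 days x $102.34/160 mg
#    gives 2149.14);
#  * hospitalization 73.38/110.08/146.77 (days x $73.78/day gives
#    73.78/110.67/147.56).
currency: USD_2022
cny_per_usd: 6.7413
wtp_per_qaly: 36036.0
discount_rate_costs: 0.05
discount_rate_outcomes: 0.05

utilities:
  base: {u_pfs: 0.84, u_pd: 0.57}
  astrum: {u_pfs: 0.94, u_pd: 0.87}
  correct: {u_pfs: 0.73, u_pd: 0.59}

dosing:
  serplulimab:
    price_per_vial: 828.92     # $ per 100 mg vial
    vial_mg: 100.0
    dose_mg_per_kg: 3.0
    weight_kg: 65.0            # assumed mean body weight
    administrations_per_cycle: 2   # q2w in a 4-week cycle
    max_duration_cycles: 26    # 2-year treatment cap
  regorafenib:
    price_per_unit: 102.34     # $ per 160 mg
    unit_mg: 160.0
    daily_mg: 160.0
    dosing_days_per_cycle: 21  # 160 mg daily for 21 of 28 days

arms:
  serplulimab:
    diagnosis_cost: 519.26
    drug_cost_per_cycle: 3315.68
    drug_cap_cycles: 26
    monitoring_pfs_y0_3: 75.65
    monitoring_pfs_y4_5: 37.83
    monitoring_pfs_gt5: 18.91
    monitoring_pd: 75.65
    admin_pfs: 2.97
    admin_pd: 1.67
    hosp_pfs: 73.38
    hosp_pd: 110.08
    subsequent_tx_pd: 749.71
    eol_cost: 2046.84
    # exposure horizon (months) for converting periodic-AE incidences
    # to per-cycle probabilities: median treatment duration assumption
    ae_rate_horizon_months: 12.0
    aes:
      - {name: anemia, incidence: 0.1081, cost: 6.96, disutility: 0.085, kind: one_off}
      - {name: hyperbilirubinemia, incidence: 0.0676, cost: 76.16, disutility: 0.0, kind: one_off}
      - {name: impaired_liver_function, incidence: 0.0541, cost: 76.16, disutility: 0.0, kind: one_off}
      - {name: alt_elevated, incidence: 0.0135, cost: 76.16, disutility: 0.0, kind: one_off}
      - {name: lung_infection, incidence: 0.0270, cost: 88.85, disutility: 0.195, kind: one_off}
      - {name: neutropenia, incidence: 0.0405, cost: 62.62, disutility: 0.0607, kind: one_off}
      - {name: leukopenia, incidence: 0.0270, cost: 62.62, disutility: 0.0607, kind: one_off}
      - {name: diarrhea, incidence: 0.0270, cost: 2.95, disutility: 0.07, kind: one_off}
      - {name: creatine_kinase_elevated, incidence: 0.0270, cost: 0.0, disutility: 0.0, kind: one_off}
      - {name: myalgia, incidence: 0.0, cost: 3.28, disutility: 0.0, kind: one_off}
      - {name: hypertension, incidence: 0.0270, cost: 0.18, disutility: 0.04, kind: periodic}
  regorafenib:
    diagnosis_cost: 519.26
    drug_cost_per_cycle: 2149.19
    drug_cap_cycles: null
    monitoring_pfs_y0_3: 113.48
    monitoring_pfs_y4_5: 37.83
    monitoring_pfs_gt5: 18.91
    monitoring_pd: 113.48
    admin_pfs: 0.0
    admin_pd: 1.80
    hosp_pfs: 0.0
    hosp_pd: 146.77
    subsequent_tx_pd: 1799.71
    eol_cost: 2046.84
    ae_rate_horizon_months: 3.0
    aes:
      - {name: hyperbilirubinemia, incidence: 0.06, cost: 37.92, disutility: 0.0, kind: one_off}
      - {name: alt_elevated, incidence: 0.07, cost: 37.92, disutility: 0.0, kind: one_off}
      - {name: ast_elevated, incidence: 0.06, cost: 37.92, disutility: 0.0, kind: one_off}
      - {name: neutropenia, incidence: 0.02, cost: 84.93, disutility: 0.0607, kind: one_off}
      - {name: leukopenia, incidence: 0.02, cost: 26.48, disutility: 0.0607, kind: one_off}
      - {name: thrombocytopenia, incidence: 0.03, cost: 2139.77, disutility: 0.19, kind: one_off}
      - {name: diarrhea, incidence: 0.01, cost: 12.04, disutility: 0.07, kind: one_off}
      - {name: hand_foot_skin_reaction, incidence: 0.16, cost: 16.18, disutility: 0.116, kind: one_off}
      - {name: maculopapular_rash, incidence: 0.04, cost: 17.63, disutility: 0.03248, kind: one_off}
      - {name: hypertension, incidence: 0.11, cost: 0.18, disutility: 0.04, kind: periodic}
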