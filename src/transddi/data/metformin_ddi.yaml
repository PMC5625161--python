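# Published clinical and in vitro inputs for the metformin transporter-DDI
# case study: perpetrator pharmacokinetics, determined IC50 (~=Ki) values,
# uptake kinetic parameters, victim renal-disposition fractions, and the
# clinically observed AUC fold-changes used for concordance scoring.
# Molecular weights are standard free-base values (g/mol).
victim: metformin
probe_conc_umol_l: 100.0
specific_activity:
  kbq_per_ml: 37.0
  conc_umol_l: 100.0
perpetrators:
  - name: cimetidine
    dose_mg: 400
    mw_g_mol: 252.34
    fu: 0.80
    cmax_total_umol_l: [9.6, 5.1]
    igut_max_umol_l: 528
  - name: trimethoprim
    dose_mg: 200
    mw_g_mol: 290.32
    fu: 0.56
    cmax_total_umol_l: [14.0, 7.6]
    igut_max_umol_l: 230
  - name: pyrimethamine
    dose_mg: 50
    mw_g_mol: 248.71
    fu: 0.13
    cmax_total_umol_l: [2.29]
    igut_max_umol_l: 67
ki_umol_l:
  cimetidine: {OCT1: 275.0, OCT2: 207.0, MATE1: 1.22, MATE2-K: 3.34}
  trimethoprim: {OCT1: 27.7, OCT2: 137.0, MATE1: 2.64, MATE2-K: 0.353}
  pyrimethamine: {OCT1: 4.46, OCT2: 4.55, MATE1: 0.131}
ki_sd_umol_l:
  cimetidine: {OCT1: 32.2, OCT2: 19.6, MATE1: 0.0870, MATE2-K: 1.02}
  trimethoprim: {OCT1: 3.80, OCT2: 58.0, MATE1: 0.271, MATE2-K: 0.0584}
  pyrimethamine: {OCT1: 0.770, OCT2: 1.12, MATE1: 0.0401}
kinetics:
  OCT1: {km_umol_l: 5422.0, km_se: 369.0, vmax_pmol_min_mg: 9370.0, vmax_se: 297.0}
  OCT2: {km_umol_l: 1608.0, km_se: 175.0, vmax_pmol_min_mg: 32918.0, vmax_se: 1165.0}
  MATE1: {km_umol_l: 4565.0, km_se: 903.0, vmax_pmol_min_mg: 141000.0, vmax_se: 12283.0}
  MATE2-K: {km_umol_l: 2986.0, km_se: 817.0, vmax_pmol_min_mg: 32147.0, vmax_se: 3401.0}
min_uptake_ratios:
  OCT1: 5
  OCT2: 18
  MATE1: 47
  MATE2-K: 9
dispositions:
  - route_label: iv
    renal_fraction_of_total_clearance: 0.88
    active_fraction_of_renal_clearance: 0.75
  - route_label: oral
    renal_fraction_of_total_clearance: 0.52
    active_fraction_of_renal_clearance: 0.75
observed:
  - {perpetrator: cimetidine, cmax_total_umol_l: 9.6, victim_dose_mg: 250, observed_fold_auc: 1.46, source_label: "cimetidine/metformin 250 mg study"}
  - {perpetrator: cimetidine, cmax_total_umol_l: 5.1, victim_dose_mg: 500, observed_fold_auc: 1.54, source_label: "cimetidine/metformin 500 mg study"}
  - {perpetrator: trimethoprim, cmax_total_umol_l: 14.0, victim_dose_mg: 500, observed_fold_auc: 1.37, source_label: "trimethoprim/metformin 500 mg study"}
  - {perpetrator: trimethoprim, cmax_total_umol_l: 7.6, victim_dose_mg: 850, observed_fold_auc: 1.30, source_label: "trimethoprim/metformin 850 mg study"}
  - {perpetrator: pyrimethamine, cmax_total_umol_l: 2.29, victim_dose_mg: 250, observed_fold_auc: 1.39, source_label: "pyrimethamine/metformin 250 mg study"}
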