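# Packaged study fixture: chronic type-B dissection, heart rate 94 bpm.
# Two otherwise identical outlet sets: case D (major branches only, 11
# outlets) and case D_min (major branches plus grouped minor branches,
# 16 outlets). Published WK3 parameters and target/simulated mean flows
# are carried per outlet; minor-branch groups list their branch counts and
# the literature-derived group flow totals (expanded to equal per-branch
# flows at load time).
name: tbad-chronic-94bpm
heart_rate_bpm: 94.0
brachial_systolic_mmHg: 138.0
brachial_diastolic_mmHg: 81.0
solver:
  dt_s: 0.001
  convergence_threshold: 0.01
  max_cycles: 50
  venous_pressure_mmHg: 0.0
metrics:
  wss_sampling_interval_s: 0.005
  ecap_threshold_per_Pa: 1.4
viscosity:
  mu0_Pa_s: 0.056
  mu_inf_Pa_s: 0.0035
  lambda_s: 3.313
  a: 2.0
  n: 0.3568
  density_kg_m3: 1056.0
seed: 0
cases:
  D:
    outlets:
      - {name: BT,  lumen: none, rho: 0.030, target_flow_mL_s: 17.10, cfd_flow_mL_s: 17.69, R_tot_mmHg_per_mL_s: 5.77,  C_mL_per_mmHg: 0.235}
      - {name: LCC, lumen: none, rho: 0.030, target_flow_mL_s: 3.84,  cfd_flow_mL_s: 3.97,  R_tot_mmHg_per_mL_s: 25.67, C_mL_per_mmHg: 0.053}
      - {name: LSA, lumen: none, rho: 0.030, target_flow_mL_s: 6.69,  cfd_flow_mL_s: 6.98,  R_tot_mmHg_per_mL_s: 14.75, C_mL_per_mmHg: 0.092}
      - {name: CT,  lumen: TL,   rho: 0.056, target_flow_mL_s: 16.31, cfd_flow_mL_s: 16.14, R_tot_mmHg_per_mL_s: 6.05,  C_mL_per_mmHg: 0.223}
      - {name: SMA, lumen: TL,   rho: 0.056, target_flow_mL_s: 14.09, cfd_flow_mL_s: 13.86, R_tot_mmHg_per_mL_s: 7.00,  C_mL_per_mmHg: 0.192}
      - {name: LRA, lumen: TL,   rho: 0.280, target_flow_mL_s: 16.59, cfd_flow_mL_s: 15.63, R_tot_mmHg_per_mL_s: 5.94,  C_mL_per_mmHg: 0.227}
      - {name: RRA, lumen: TL,   rho: 0.280, target_flow_mL_s: 12.64, cfd_flow_mL_s: 12.25, R_tot_mmHg_per_mL_s: 7.80,  C_mL_per_mmHg: 0.173}
      - {name: LEI, lumen: TL,   rho: 0.056, target_flow_mL_s: 9.61,  cfd_flow_mL_s: 9.60,  R_tot_mmHg_per_mL_s: 10.26, C_mL_per_mmHg: 0.131}
      - {name: LII, lumen: TL,   rho: 0.056, target_flow_mL_s: 4.76,  cfd_flow_mL_s: 4.76,  R_tot_mmHg_per_mL_s: 20.72, C_mL_per_mmHg: 0.065}
      - {name: REI, lumen: TL,   rho: 0.056, target_flow_mL_s: 5.21,  cfd_flow_mL_s: 5.41,  R_tot_mmHg_per_mL_s: 18.95, C_mL_per_mmHg: 0.071}
      - {name: RII, lumen: TL,   rho: 0.056, target_flow_mL_s: 3.01,  cfd_flow_mL_s: 3.17,  R_tot_mmHg_per_mL_s: 32.79, C_mL_per_mmHg: 0.041}
  D_min:
    outlets:
      - {name: BT,  lumen: none, rho: 0.030, target_flow_mL_s: 17.10, cfd_flow_mL_s: 17.39, R_tot_mmHg_per_mL_s: 5.77,  C_mL_per_mmHg: 0.235}
      - {name: LCC, lumen: none, rho: 0.030, target_flow_mL_s: 3.84,  cfd_flow_mL_s: 3.88,  R_tot_mmHg_per_mL_s: 25.67, C_mL_per_mmHg: 0.053}
      - {name: LSA, lumen: none, rho: 0.030, target_flow_mL_s: 6.69,  cfd_flow_mL_s: 6.80,  R_tot_mmHg_per_mL_s: 14.75, C_mL_per_mmHg: 0.092}
      - {name: S1,  lumen: FL,   rho: 0.056, target_flow_mL_s: 5.50,  cfd_flow_mL_s: 5.09,  R_tot_mmHg_per_mL_s: 17.93, C_mL_per_mmHg: 0.075, n_branches: 7}
      - {name: S2,  lumen: TL,   rho: 0.056, target_flow_mL_s: 7.97,  cfd_flow_mL_s: 7.43,  R_tot_mmHg_per_mL_s: 12.37, C_mL_per_mmHg: 0.109, n_branches: 11}
      - {name: S3,  lumen: FL,   rho: 0.056, target_flow_mL_s: 2.11,  cfd_flow_mL_s: 1.89,  R_tot_mmHg_per_mL_s: 46.79, C_mL_per_mmHg: 0.029, n_branches: 2}
      - {name: CT,  lumen: TL,   rho: 0.056, target_flow_mL_s: 12.38, cfd_flow_mL_s: 12.39, R_tot_mmHg_per_mL_s: 7.97,  C_mL_per_mmHg: 0.170}
      - {name: SMA, lumen: TL,   rho: 0.056, target_flow_mL_s: 10.70, cfd_flow_mL_s: 10.72, R_tot_mmHg_per_mL_s: 9.22,  C_mL_per_mmHg: 0.147}
      - {name: LRA, lumen: TL,   rho: 0.280, target_flow_mL_s: 12.20, cfd_flow_mL_s: 12.10, R_tot_mmHg_per_mL_s: 8.09,  C_mL_per_mmHg: 0.167}
      - {name: RRA, lumen: TL,   rho: 0.280, target_flow_mL_s: 9.20,  cfd_flow_mL_s: 9.23,  R_tot_mmHg_per_mL_s: 10.72, C_mL_per_mmHg: 0.126}
      - {name: S4,  lumen: FL,   rho: 0.056, target_flow_mL_s: 4.29,  cfd_flow_mL_s: 3.98,  R_tot_mmHg_per_mL_s: 23.01, C_mL_per_mmHg: 0.059, n_branches: 8}
      - {name: IMA, lumen: TL,   rho: 0.056, target_flow_mL_s: 1.93,  cfd_flow_mL_s: 1.71,  R_tot_mmHg_per_mL_s: 51.12, C_mL_per_mmHg: 0.026}
      - {name: LEI, lumen: TL,   rho: 0.056, target_flow_mL_s: 6.77,  cfd_flow_mL_s: 6.87,  R_tot_mmHg_per_mL_s: 13.57, C_mL_per_mmHg: 0.093}
      - {name: LII, lumen: TL,   rho: 0.056, target_flow_mL_s: 3.35,  cfd_flow_mL_s: 3.38,  R_tot_mmHg_per_mL_s: 27.39, C_mL_per_mmHg: 0.046}
      - {name: REI, lumen: TL,   rho: 0.056, target_flow_mL_s: 3.40,  cfd_flow_mL_s: 3.46,  R_tot_mmHg_per_mL_s: 26.97, C_mL_per_mmHg: 0.047}
      - {name: RII, lumen: TL,   rho: 0.056, target_flow_mL_s: 1.97,  cfd_flow_mL_s: 1.99,  R_tot_mmHg_per_mL_s: 46.67, C_mL_per_mmHg: 0.027}
# Literature-derived (Doppler) minor-branch group flow totals; individual
# branches within a group default to equal flow (the study assumes constant
# minor-branch diameter).
minor_branch_groups:
  S1:  {n_branches: 7,  total_flow_mL_s: 5.50}
  S2:  {n_branches: 11, total_flow_mL_s: 7.97}
  S3:  {n_branches: 2,  total_flow_mL_s: 2.11}
  S4:  {n_branches: 8,  total_flow_mL_s: 4.29}
  IMA: {n_branches: 1,  total_flow_mL_s: 1.93}
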