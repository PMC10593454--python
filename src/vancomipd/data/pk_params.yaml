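# Final population PK model estimates: two-compartment vancomycin model
# with allometric scaling, renal-function factor, maturation factor and
# covariate effects on clearance and central volume.
theta_cl: 4.32        # L/h, typical clearance at 70 kg
theta_v: 38.6         # L, typical central volume at 70 kg
theta_q: 3.93         # L/h, inter-compartmental clearance
theta_v2: 66.8        # L, peripheral volume
k_cr_older: -0.0127   # 1/yr, creatinine production slope, age >= 30
k_cr_younger: 0.0193  # 1/yr, creatinine production slope, age < 30
lambda: 0.655         # renal factor exponent
pma50: 43.9           # weeks, half-maximal maturation
gamma: 2.08           # maturation sigmoid steepness
k_tox: 0.00598        # 1/day, nephrotoxic CLCr decline
k_v: 0.00957          # 1/yr, central volume age slope
k_bun: -0.00874       # dL/mg, BUN slope on clearance
theta_ren: -0.237     # renal disease fraction on CL
theta_fem: -0.199     # female fraction on CL
theta_dm: -0.151      # diabetes fraction on CL
omega_cl: 0.291       # SD of log-scale BSV on CL
omega_v2: 1.01        # SD of log-scale BSV on V2
sigma_prop_trough: 0.178
sigma_add_trough: 0.956   # mg/L
sigma_prop_peak: 0.110
sigma_add_peak: 4.47      # mg/L
rcr_ref: 64.2         # mg/h, creatinine production at age 30
cr_ref: 1.0           # mg/dL, reference creatinine defining CLCr_TV
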