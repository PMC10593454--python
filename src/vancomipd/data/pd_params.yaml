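# Final CRP transit-compartment PD model estimates.  k_crp is fixed from
# the 19-h CRP half-life (ln 2 / 19 = 0.0365 per hour).
theta_ktr: 0.0129   # 1/h, base transit rate
theta_pne: 0.0058   # 1/h, pneumonia shift on ktr
k_crp: 0.0365       # 1/h, CRP elimination rate (fixed)
crp0: 110.0         # mg/L, baseline CRP
k_d: 0.00192        # 1/h, disease progression rate
alpha: 0.000239     # per mg.h/L, drug-effect scale on cumulative AUC
s_crp: 102.0        # severity scaling on CRP production
omega_kd: 1.476     # SD of log-scale BSV on kD
omega_crp0: 1.072   # SD of log-scale BSV on CRP0
sigma_prop: 0.549   # proportional residual SD
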