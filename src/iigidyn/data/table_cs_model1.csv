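# Reference per-subject parameter estimates, IIGI cohort, Hill variant (model 1),
# control subjects (CS). Units: a1 (10 pM min)^-1, a2 mg/dL (pM min)^-1,
# gamma1 10 pM/min, gamma2 pM/min, k1 and k2 mM^-1, h dimensionless,
# tau and tau1 min. Dash cells of the source table (no delay) are encoded as 0.
subject,a1,a2,gamma1,gamma2,k1,k2,h,tau,tau1
1,0.00061,0.33,8.7,1.7,0.25,0.55,2.0,0,0
2,0.000055,0.052,9.3,1.3,0.046,0.35,1.4,3.0,12
3,0.00071,0.20,8.7,3.6,0.27,0.55,2.2,5.3,0
4,0.00012,0.068,21,8.1,0.26,0.45,1.9,0,0
5,0.00032,0.28,3.2,3.4,0.48,0.55,1.3,0,0
7,0.0012,0.59,8.9,0.92,0.24,0.50,2.3,0,0
8,0.00063,0.25,3.2,2.9,0.28,0.55,1.9,0,0
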