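# Reference per-subject parameter estimates, IIGI cohort, hysteresis variant
# (model 2), control subjects (CS). h1/h2 are the rising/falling Hill
# coefficients; other units as in the model-1 tables. Dash cells encoded as 0.
subject,a1,a2,gamma1,gamma2,k1,k2,h1,h2,tau1,tau
1,0.00053,0.34,6.0,2.9,0.35,0.55,1.4,1.8,0,0
2,0.000058,0.092,9.0,2.0,0.077,0.35,1.3,1.8,14,3.5
3,0.00062,0.18,5.7,4.7,0.31,0.55,1.4,2.3,6,5
4,0.00011,0.070,16,8.8,0.28,0.55,1.1,2.2,0,0
5,0.00034,0.28,2.7,3.3,0.46,0.45,0.94,1.4,0,0
7,0.0011,0.58,8.6,0.96,0.24,0.55,2.2,2.4,0,0
8,0.00063,0.22,2.7,2.9,0.25,0.45,1.3,1.7,0,0
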