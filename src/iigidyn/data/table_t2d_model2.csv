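# Reference per-subject parameter estimates, IIGI cohort, hysteresis variant
# (model 2), patients with type 2 diabetes (T2D). Dash cells encoded as 0.
subject,a1,a2,gamma1,gamma2,k1,k2,h1,h2,tau1,tau
1,0.000092,0.33,2.6,2.5,0.17,0.4,1.2,1.3,30,10
2,0.000075,0.57,4.5,3.6,0.18,0.35,1.4,2.0,30,8
3,0.000081,0.45,9.2,2.1,0.13,0.65,2.3,2.0,30,10
5,0.000072,0.26,4.5,4.5,0.14,0.41,1.5,1.4,30,12
6,0.0001,0.19,5.4,4.2,0.097,0.65,0.9,0.95,45,10
7,0.00011,0.18,2.0,1.1,0.15,0.45,1.1,0.90,0,0
8,0.00011,0.12,10,5.1,0.18,0.3,2.2,1.2,15,0
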