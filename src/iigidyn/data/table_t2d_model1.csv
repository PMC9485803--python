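# Reference per-subject parameter estimates, IIGI cohort, Hill variant (model 1),
# patients with type 2 diabetes (T2D). Units as in the CS table.
# Dash cells of the source table (no delay) are encoded as 0.
subject,a1,a2,gamma1,gamma2,k1,k2,h,tau,tau1
1,0.00010,0.30,2.7,2.8,0.17,0.60,1.1,10,30
2,0.000085,0.50,4.2,3.6,0.17,0.45,1.7,8,30
3,0.000094,0.49,8.9,1.9,0.13,0.65,1.8,10,35
5,0.000072,0.29,4.6,4.0,0.14,0.33,1.6,12,30
6,0.000050,0.16,5.8,5.2,0.10,0.65,1.0,10,45
7,0.00011,0.18,2.0,1.4,0.16,0.45,1.0,0,0
8,0.000080,0.11,10,8.6,0.23,0.45,1.9,0,15
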