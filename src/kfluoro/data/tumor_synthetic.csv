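energy_keV,mu_total_per_cm
10,5.32253
12,3.15456
14,2.05937
16,1.44755
18,1.07914
20,0.844
22,0.686762
24,0.577519
26,0.499152
28,0.441382
30,0.397782
33,0.350247
36,0.316832
40,0.285903
45,0.260381
50,0.243361
55,0.231387
60,0.222578
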