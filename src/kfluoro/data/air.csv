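energy_keV,mu_total_per_cm,mu_en_rho_cm2_g
8,0.0119656,9.446
10,0.0061696,4.742
15,0.00194487,1.334
20,0.00093737,0.5389
25,0.00060732,0.27
30,0.000426329,0.1537
35,0.000352704,0.0994
40,0.000299442,0.06833
45,0.000272571,0.05216
50,0.00025064,0.04098
55,0.000237385,0.03506
60,0.000225937,0.03041
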