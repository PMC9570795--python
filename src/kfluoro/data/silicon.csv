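energy_keV,mu_total_per_cm,mu_pe_per_cm
8,151.45,149.819
10,78.9637,77.589
15,24.0922,23.1136
20,10.4011,9.6229
25,5.67355,5.0095
30,3.34588,2.796
35,2.17296,1.7242
40,1.6338,1.20461
45,1.27451,0.85045
50,1.02171,0.61745
55,0.86676,0.466
60,0.747231,0.35416
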