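energy_keV,mu_total_per_cm,mu_pe_per_cm
8,1503.65,1488.86
10,798.167,785.349
12,472.294,459.969
15,271.742,260.797
20,125.37,116.348
25,68.8721,61.132
30,42.2057,36.2355
33.16,32.3063,27.115
33.18,176.593,171.071
35,153.323,148.393
40,108.953,105.009
45,79.373,75.922
50,60.7376,57.681
55,47.8703,44.863
60,37.3694,34.7565
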