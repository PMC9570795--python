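energy_keV,mu_total_per_cm
8.5,2054
10,1738
15,711
20,327.85
25,183.28
30,114.55
35,76.63
40,56.09
45,39.974
50,29.625
50.23,29.467
50.25,146.15
55,114.55
60,90.85
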