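energy_keV,mu_total_per_cm
8,135.841
10,70.7948
15,21.4705
20,9.28726
25,4.93377
30,3.04447
35,2.10522
40,1.53438
45,1.21968
50,0.993502
55,0.857742
60,0.749782
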