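energy_keV,mu_total_per_cm
10,5.01062
12,2.97349
14,1.94432
16,1.36933
18,1.02305
20,0.802
22,0.654157
24,0.551418
26,0.477698
28,0.423337
30,0.382296
33,0.337529
36,0.306039
40,0.276866
45,0.252762
50,0.236661
55,0.225312
60,0.216947
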