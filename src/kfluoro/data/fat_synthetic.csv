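energy_keV,mu_total_per_cm
10,2.48122
12,1.49513
14,1.0005
16,0.725619
18,0.56071
20,0.4557
22,0.385549
24,0.336799
26,0.301775
28,0.275887
30,0.256274
33,0.234755
36,0.219478
40,0.205135
45,0.193031
50,0.184719
55,0.178675
60,0.174072
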