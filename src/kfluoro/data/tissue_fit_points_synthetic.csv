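material,energy_keV,mu_total_per_cm
fat,14,1.0005
fat,16,0.725619
fat,18,0.56071
fat,20,0.4557
fat,22,0.385549
fat,24,0.336799
fat,26,0.301775
fat,28,0.275887
fat,30,0.256274
fibrous,14,1.94432
fibrous,16,1.36933
fibrous,18,1.02305
fibrous,20,0.802
fibrous,22,0.654157
fibrous,24,0.551418
fibrous,26,0.477698
fibrous,28,0.423337
fibrous,30,0.382296
tumor,14,2.05937
tumor,16,1.44755
tumor,18,1.07914
tumor,20,0.844
tumor,22,0.686762
tumor,24,0.577519
tumor,26,0.499152
tumor,28,0.441382
tumor,30,0.397782
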