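energy_keV,k_shell_fraction
33.18,0.865
35,0.866
40,0.868
45,0.869
50,0.87
55,0.871
60,0.872
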