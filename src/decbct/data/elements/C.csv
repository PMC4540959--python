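energy_keV,mu_over_rho_cm2_g
10,2.373
15,0.8071
20,0.4420
30,0.2562
40,0.2076
50,0.1871
60,0.1753
80,0.1610
100,0.1514
150,0.1347
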