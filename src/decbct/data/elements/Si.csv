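energy_keV,mu_over_rho_cm2_g
10,33.89
15,10.34
20,4.464
30,1.436
40,0.7012
50,0.4385
60,0.3207
80,0.2228
100,0.1835
150,0.1448
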