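energy_keV,mu_over_rho_cm2_g
10,3.879
15,1.236
20,0.6178
30,0.3066
40,0.2288
50,0.1980
60,0.1817
80,0.1639
100,0.1529
150,0.1353
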