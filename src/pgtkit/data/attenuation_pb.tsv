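# total photon mass attenuation coefficients (with coherent), lead
# density_g_cm3 = 11.35
# E_MeV	mu_over_rho_cm2_g
0.02	86.3741
0.03	30.3211
0.04	14.3583
0.05	8.04199
0.06	5.01967
0.08	2.41954
0.09	7.2552
0.1	5.54875
0.14	2.39009
0.2	0.998688
0.3	0.403178
0.4	0.232268
0.5	0.161356
0.6	0.124755
0.8	0.0887017
1	0.0735091
1.25	0.05876
1.5	0.05222
2	0.04606
3	0.04234
4	0.04197
5	0.04272
6	0.04391
8	0.04675
10	0.04972
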