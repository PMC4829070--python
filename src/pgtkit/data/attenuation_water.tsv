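# total photon mass attenuation coefficients (with coherent), water
# density_g_cm3 = 1.0
# E_MeV	mu_over_rho_cm2_g
0.02	0.809825
0.03	0.375595
0.04	0.268276
0.05	0.226937
0.06	0.205874
0.08	0.183657
0.09	0.176555
0.1	0.170725
0.14	0.153827
0.2	0.137022
0.3	0.118637
0.4	0.106138
0.5	0.0968729
0.6	0.0895621
0.8	0.0786582
1	0.0706611
1.25	0.06323
1.5	0.05754
2	0.04942
3	0.03969
4	0.03403
5	0.03031
6	0.0277
8	0.02429
10	0.02219
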