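# total photon mass attenuation coefficients (with coherent), cesium iodide
# density_g_cm3 = 4.51
# E_MeV	mu_over_rho_cm2_g
0.02	26.8589
0.03	9.04657
0.04	22.9696
0.05	12.8723
0.06	7.92118
0.08	3.67708
0.09	2.68835
0.1	2.03535
0.14	0.862136
0.2	0.380526
0.3	0.181803
0.4	0.123727
0.5	0.0980924
0.6	0.0837375
0.8	0.0676972
1	0.0592104
1.25	0.0521124
1.5	0.0468631
2	0.0396857
3	0.0360715
4	0.0349944
5	0.0348823
6	0.0352106
8	0.0364507
10	0.0380003
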