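# SYNTHETIC flow curve: generated from the power-law model
# eta = 1.04 * gamma^(0.0511 - 1) (24.5 wt% Pluronic F-127 constants),
# noiseless, 25 log-spaced shear rates. Not a measured rheometer sweep.
shear_rate_1/s,viscosity_Pa_s
0.01,82.19271745
0.01643124492,51.30782811
0.02699858096,32.0283026
0.04436202961,19.99328767
0.07289233736,12.48057248
0.1197711848,7.790849206
0.1967989671,4.863345127
0.3233652028,3.03588546
0.5313292846,1.895115458
0.8730401607,1.183003327
1.43451367,0.7384757826
2.357084546,0.4609847405
3.872983346,0.2877642516
6.363793792,0.1796334179
10.45650544,0.1121340286
17.18134019,0.06999833614
28.23108087,0.04369563035
46.3871804,0.02727647851
76.21991222,0.0170270179
125.2388045,0.01062891379
205.7829471,0.006634973249
338.1270003,0.004141803283
555.5847555,0.00258547153
912.8949191,0.001613949909
1500,0.001007489071
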