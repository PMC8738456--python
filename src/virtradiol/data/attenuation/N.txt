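# energy_keV  mu_over_rho_cm2_g
1 33243.4
1.09396 23479.9
1.19674 16585
1.30919 11715.7
1.43219 8276.79
1.56676 5847.95
1.71397 4132.41
1.87501 2920.59
2.05118 2064.52
2.24391 1459.7
2.45474 1032.34
2.68538 730.331
2.93769 516.869
3.21371 365.964
3.51566 259.257
3.84599 183.784
4.20735 130.385
4.60266 92.5892
5.03511 65.8256
5.5082 46.8641
6.02574 33.4218
6.5919 23.8854
7.21126 17.1141
7.88881 12.3013
8.63003 8.87661
9.44089 6.43624
10.3279 4.6945
11.2983 3.44905
12.3599 2.55652
13.5212 1.91528
14.7916 1.45321
16.1814 1.1191
17.7018 0.876555
19.365 0.699668
21.1845 0.569976
23.1749 0.4743
25.3524 0.403215
27.7344 0.349965
30.3403 0.309697
33.191 0.278913
36.3095 0.255086
39.7211 0.236381
43.4532 0.221463
47.5359 0.209354
52.0023 0.199336
56.8883 0.19088
62.2334 0.183591
68.0807 0.177176
74.4774 0.171417
81.4751 0.166148
89.1303 0.161245
97.5048 0.156617
106.666 0.152193
116.688 0.147922
127.652 0.143766
139.646 0.139696
152.767 0.135694
167.12 0.131748
182.822 0.127848
200 0.123991
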