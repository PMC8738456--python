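# energy_keV  mu_over_rho_cm2_g
1 67.0756
1.09396 48.3734
1.19674 35.021
1.30919 25.47
1.43219 18.6234
1.56676 13.7031
1.71397 10.157
1.87501 7.59301
2.05118 5.73234
2.24391 4.37649
2.45474 3.38398
2.68538 2.65375
2.93769 2.11352
3.21371 1.71146
3.51566 1.41031
3.84599 1.1832
4.20735 1.01071
4.60266 0.878733
5.03511 0.776977
5.5082 0.697914
6.02574 0.635997
6.5919 0.587121
7.21126 0.548229
7.88881 0.517027
8.63003 0.491784
9.44089 0.471184
10.3279 0.45422
11.2983 0.440111
12.3599 0.428254
13.5212 0.418172
14.7916 0.409489
16.1814 0.401908
17.7018 0.395187
19.365 0.389133
21.1845 0.383587
23.1749 0.378419
25.3524 0.373524
27.7344 0.368811
30.3403 0.364209
33.191 0.359654
36.3095 0.355096
39.7211 0.350492
43.4532 0.345806
47.5359 0.34101
52.0023 0.33608
56.8883 0.330998
62.2334 0.32575
68.0807 0.320327
74.4774 0.314724
81.4751 0.308939
89.1303 0.302975
97.5048 0.296837
106.666 0.290534
116.688 0.284078
127.652 0.277482
139.646 0.270762
152.767 0.263937
167.12 0.257025
182.822 0.250046
200 0.24302
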