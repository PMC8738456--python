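# energy_keV  mu_over_rho_cm2_g
1 1.45103e+06
1.09396 1.02454e+06
1.19674 723406
1.30919 510787
1.43219 360664
1.56676 254666
1.71397 179823
1.87501 126977
2.05118 89663.5
2.24391 63316.3
2.45474 44712.4
2.68538 31575.9
2.93769 22299.7
3.21371 15749.4
3.51566 11123.8
3.84599 7857.27
4.20735 5550.4
4.60266 3921.19
5.03511 2770.51
5.5082 1957.77
6.02574 1383.67
6.5919 978.104
7.21126 691.576
7.88881 489.12
8.63003 346.048
9.44089 244.925
10.3279 173.439
11.2983 122.891
12.3599 87.1391
13.5212 61.8443
14.7916 43.9412
16.1814 31.264
17.7018 22.2826
19.365 15.9156
21.1845 11.3985
23.1749 8.19108
25.3524 5.91122
27.7344 4.28866
30.3403 3.13219
33.191 2.30647
36.3095 1.71565
39.7211 1.29185
43.4532 0.986911
47.5359 0.766699
52.0023 0.606961
56.8883 0.490464
62.2334 0.404947
68.0807 0.341673
74.4774 0.294409
81.4751 0.2587
89.1303 0.231358
97.5048 0.210093
106.666 0.193262
116.688 0.179678
127.652 0.168484
139.646 0.15906
152.767 0.150957
167.12 0.143846
182.822 0.137487
200 0.131707
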