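# energy_keV  mu_over_rho_cm2_g
1 5.05518e+06
1.09396 3.56926e+06
1.19674 2.52012e+06
1.30919 1.77937e+06
1.43219 1.25636e+06
1.56676 887081
1.71397 626348
1.87501 442253
2.05118 312270
2.24391 220493
2.45474 155692
2.68538 109936
2.93769 77629.4
3.21371 54817.6
3.51566 38710.1
3.84599 27336.5
4.20735 19305.3
4.60266 13634.1
5.03511 9629.45
5.5082 6801.45
6.02574 4804.33
6.5919 3393.91
7.21126 2397.8
7.88881 1694.26
8.63003 1197.31
9.44089 846.28
10.3279 598.289
11.2983 423.077
12.3599 299.269
13.5212 211.771
14.7916 149.924
16.1814 106.199
17.7018 75.2775
19.365 53.4049
21.1845 37.9275
23.1749 26.971
25.3524 19.2112
27.7344 13.7122
30.3403 9.81258
33.191 7.04498
36.3095 5.07885
39.7211 3.68047
43.4532 2.68448
47.5359 1.97389
52.0023 1.46589
56.8883 1.10182
62.2334 0.8401
68.0807 0.651266
74.4774 0.514401
81.4751 0.414652
89.1303 0.341459
97.5048 0.287306
106.666 0.246838
116.688 0.216233
127.652 0.192761
139.646 0.174466
152.767 0.159944
167.12 0.148187
182.822 0.138468
200 0.130264
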