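# energy_keV  mu_over_rho_cm2_g
1 2.17116e+06
1.09396 1.53299e+06
1.19674 1.0824e+06
1.30919 764259
1.43219 539630
1.56676 381026
1.71397 269041
1.87501 189971
2.05118 134142
2.24391 94721.2
2.45474 66886.7
2.68538 47232.7
2.93769 33354.9
3.21371 23555.4
3.51566 16635.7
3.84599 11749.3
4.20735 8298.65
4.60266 5861.84
5.03511 4140.92
5.5082 2925.52
6.02574 2067.09
6.5919 1460.76
7.21126 1032.46
7.88881 729.882
8.63003 516.108
9.44089 365.053
10.3279 258.302
11.2983 182.847
12.3599 129.502
13.5212 91.7801
14.7916 65.0976
16.1814 46.2177
17.7018 32.8533
19.365 23.3888
21.1845 16.6823
23.1749 11.9271
25.3524 8.55272
27.7344 6.156
30.3403 4.45179
33.191 3.23839
36.3095 2.37307
39.7211 1.75482
43.4532 1.31207
47.5359 0.994139
52.0023 0.765069
56.8883 0.599353
62.2334 0.478876
68.0807 0.390762
74.4774 0.325844
81.4751 0.277591
89.1303 0.241342
97.5048 0.213764
106.666 0.192472
116.688 0.175752
127.652 0.162374
139.646 0.151451
152.767 0.14234
167.12 0.134578
182.822 0.127827
200 0.121843
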