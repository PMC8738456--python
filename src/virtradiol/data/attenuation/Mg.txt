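# energy_keV  mu_over_rho_cm2_g
1 228330
1.09396 161230
1.19674 113852
1.30919 80397.9
1.43219 56775.6
1.56676 40095.4
1.71397 28316.9
1.87501 19999.5
2.05118 14125.9
2.24391 9978.06
2.45474 7048.73
2.68538 4979.89
2.93769 3518.67
3.21371 2486.56
3.51566 1757.49
3.84599 1242.43
4.20735 878.53
4.60266 621.391
5.03511 439.666
5.5082 311.215
6.02574 220.402
6.5919 156.183
7.21126 110.757
7.88881 78.613
8.63003 55.8591
9.44089 39.7445
10.3279 28.3256
11.2983 20.2287
12.3599 14.483
13.5212 10.4021
14.7916 7.50049
16.1814 5.43476
17.7018 3.96194
19.365 2.91002
21.1845 2.15716
23.1749 1.61703
25.3524 1.22841
27.7344 0.94784
30.3403 0.744471
33.191 0.596356
36.3095 0.487871
39.7211 0.407879
43.4532 0.348424
47.5359 0.303815
52.0023 0.269971
56.8883 0.243958
62.2334 0.223663
68.0807 0.207557
74.4774 0.194533
81.4751 0.183783
89.1303 0.17472
97.5048 0.166913
106.666 0.160045
116.688 0.153884
127.652 0.148258
139.646 0.14304
152.767 0.138137
167.12 0.133481
182.822 0.129021
200 0.124721
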