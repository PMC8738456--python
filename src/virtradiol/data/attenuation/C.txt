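# energy_keV  mu_over_rho_cm2_g
1 19091.6
1.09396 13486.3
1.19674 9527.56
1.30919 6731.61
1.43219 4756.78
1.56676 3361.81
1.71397 2376.37
1.87501 1680.15
2.05118 1188.22
2.24391 840.576
2.45474 594.866
2.68538 421.165
2.93769 298.343
3.21371 211.473
3.51566 150.012
3.84599 106.511
4.20735 75.7093
4.60266 53.8876
5.03511 38.4186
5.5082 27.445
6.02574 19.6539
6.5919 14.1168
7.21126 10.1771
7.88881 7.37012
8.63003 5.36706
9.44089 3.93504
10.3279 2.90906
11.2983 2.17217
12.3599 1.64138
13.5212 1.25777
14.7916 0.979471
16.1814 0.776673
17.7018 0.628143
19.365 0.518723
21.1845 0.437576
23.1749 0.376934
25.3524 0.33122
27.7344 0.296415
30.3403 0.269613
33.191 0.248707
36.3095 0.232165
39.7211 0.218862
43.4532 0.207974
47.5359 0.198892
52.0023 0.191163
56.8883 0.184448
62.2334 0.178495
68.0807 0.173112
74.4774 0.168154
81.4751 0.163514
89.1303 0.159107
97.5048 0.154872
106.666 0.150762
116.688 0.146742
127.652 0.142789
139.646 0.138885
152.767 0.135017
167.12 0.131181
182.822 0.127371
200 0.123589
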