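# energy_keV  mu_over_rho_cm2_g
1 1.84888e+08
1.09396 1.3054e+08
1.19674 9.21679e+07
1.30919 6.50751e+07
1.43219 4.59463e+07
1.56676 3.24404e+07
1.71397 2.29046e+07
1.87501 1.61718e+07
2.05118 1.14181e+07
2.24391 8.06182e+06
2.45474 5.69208e+06
2.68538 4.01893e+06
2.93769 2.83759e+06
3.21371 2.0035e+06
3.51566 1.4146e+06
3.84599 998794
4.20735 705214
4.60266 497930
5.03511 351575
5.5082 248239
6.02574 175277
6.5919 123762
7.21126 87387.8
7.88881 61705.1
8.63003 43571.1
9.44089 30766.9
10.3279 21725.9
11.2983 15342.1
12.3599 10834.4
13.5212 7651.36
14.7916 5403.72
16.1814 3816.55
17.7018 2695.72
19.365 1904.2
21.1845 1345.21
23.1749 950.417
25.3524 671.577
27.7344 474.621
30.3403 335.492
33.191 237.203
36.3095 167.758
39.7211 118.687
43.4532 84.0063
47.5359 59.4919
52.0023 42.1597
56.8883 29.9025
62.2334 21.2314
68.0807 15.0951
74.4774 10.7505
81.4751 7.6729
89.1303 5.49132
97.5048 3.94368
106.666 2.84468
116.688 2.06334
127.652 1.50702
139.646 1.1102
152.767 0.826511
167.12 0.623139
182.822 0.476839
200 0.371143
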