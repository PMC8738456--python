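# energy_keV  mu_over_rho_cm2_g
1 499971
1.09396 353029
1.19674 249276
1.30919 176019
1.43219 124293
1.56676 87769
1.71397 61979.5
1.87501 43769.2
2.05118 30910.5
2.24391 21830.4
2.45474 15418.4
2.68538 10890.4
2.93769 7692.74
3.21371 5434.45
3.51566 3839.51
3.84599 2712.99
4.20735 1917.28
4.60266 1355.19
5.03511 958.085
5.5082 677.515
6.02574 479.253
6.5919 339.133
7.21126 240.086
7.88881 170.057
8.63003 120.533
9.44089 85.4985
10.3279 60.7064
11.2983 43.1547
12.3599 30.7228
13.5212 21.9122
14.7916 15.6638
16.1814 11.229
17.7018 8.07822
19.365 5.83728
21.1845 4.24132
23.1749 3.1029
25.3524 2.28934
27.7344 1.70665
30.3403 1.28821
33.191 0.986782
36.3095 0.768832
39.7211 0.610535
43.4532 0.494947
47.5359 0.41
52.0023 0.347089
56.8883 0.300067
62.2334 0.264535
68.0807 0.237336
74.4774 0.216204
81.4751 0.199502
89.1303 0.18605
97.5048 0.174992
106.666 0.165704
116.688 0.157734
127.652 0.150751
139.646 0.144511
152.767 0.138837
167.12 0.133597
182.822 0.128697
200 0.124066
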