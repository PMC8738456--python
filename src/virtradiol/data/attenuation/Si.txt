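# energy_keV  mu_over_rho_cm2_g
1 401479
1.09396 283487
1.19674 200175
1.30919 141350
1.43219 99813.6
1.56676 70484.8
1.71397 49775.3
1.87501 35151.8
2.05118 24825.7
2.24391 17533.8
2.45474 12384.4
2.68538 8747.99
2.93769 6179.84
3.21371 4366.06
3.51566 3084.99
3.84599 2180.12
4.20735 1540.93
4.60266 1089.36
5.03511 770.315
5.5082 544.87
6.02574 385.541
6.5919 272.918
7.21126 193.294
7.88881 136.987
8.63003 97.1555
9.44089 68.9702
10.3279 49.0177
11.2983 34.8863
12.3599 24.8722
13.5212 17.771
14.7916 12.7315
16.1814 9.15176
17.7018 6.60617
19.365 4.79364
21.1845 3.5011
23.1749 2.5777
25.3524 1.91661
27.7344 1.44212
30.3403 1.10053
33.191 0.853737
36.3095 0.674671
39.7211 0.544084
43.4532 0.448269
47.5359 0.377453
52.0023 0.324659
56.8883 0.284891
62.2334 0.254568
68.0807 0.231117
74.4774 0.212683
81.4751 0.197926
89.1303 0.185875
97.5048 0.175824
106.666 0.167257
116.688 0.159799
127.652 0.153175
139.646 0.147181
152.767 0.14167
167.12 0.136531
182.822 0.131685
200 0.127072
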