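# energy_keV  mu_over_rho_cm2_g
1 161788
1.09396 114246
1.19674 80676.4
1.30919 56972.5
1.43219 40234.6
1.56676 28415.3
1.71397 20069
1.87501 14175.1
2.05118 10012.9
2.24391 7073.38
2.45474 4997.34
2.68538 3531.04
2.93769 2495.33
3.21371 1763.71
3.51566 1246.85
3.84599 881.67
4.20735 623.625
4.60266 441.258
5.03511 312.35
5.5082 221.213
6.02574 156.763
6.5919 111.172
7.21126 78.9112
7.88881 56.0734
8.63003 39.8988
9.44089 28.4367
10.3279 20.3088
11.2983 14.5408
12.3599 10.4436
13.5212 7.5302
14.7916 5.4559
16.1814 3.97681
17.7018 2.92029
19.365 2.16404
21.1845 1.62142
23.1749 1.23096
25.3524 0.949035
27.7344 0.744672
30.3403 0.595834
33.191 0.486831
36.3095 0.406476
39.7211 0.346778
43.4532 0.302019
47.5359 0.268097
52.0023 0.242063
56.8883 0.22179
62.2334 0.205741
68.0807 0.192801
74.4774 0.182155
81.4751 0.173212
89.1303 0.165535
97.5048 0.158804
106.666 0.152784
116.688 0.1473
127.652 0.142224
139.646 0.137459
152.767 0.132936
167.12 0.128603
182.822 0.124424
200 0.12037
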