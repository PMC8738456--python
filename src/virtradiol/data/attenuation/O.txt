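# energy_keV  mu_over_rho_cm2_g
1 53766.7
1.09396 37972.1
1.19674 26818.8
1.30919 18942.5
1.43219 13380.4
1.56676 9452.24
1.71397 6677.96
1.87501 4718.51
2.05118 3334.46
2.24391 2356.78
2.45474 1666.1
2.68538 1178.1
2.93769 833.276
3.21371 589.578
3.51566 417.32
3.84599 295.535
4.20735 209.412
4.60266 148.492
5.03511 105.384
5.5082 74.8675
6.02574 53.2551
6.5919 37.94
7.21126 27.0803
7.88881 19.3738
8.63003 13.9001
9.44089 10.0082
10.3279 7.2374
11.2983 5.26197
12.3599 3.85117
13.5212 2.8416
14.7916 2.11747
16.1814 1.59665
17.7018 1.22088
19.365 0.948763
21.1845 0.750853
23.1749 0.606193
25.3524 0.49984
27.7344 0.421118
30.3403 0.362388
33.191 0.31817
36.3095 0.284525
39.7211 0.258609
43.4532 0.238366
47.5359 0.222304
52.0023 0.209332
56.8883 0.198653
62.2334 0.189681
68.0807 0.181983
74.4774 0.175238
81.4751 0.169207
89.1303 0.16371
97.5048 0.158616
106.666 0.153824
116.688 0.149259
127.652 0.144868
139.646 0.14061
152.767 0.136456
167.12 0.132386
182.822 0.128385
200 0.124445
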