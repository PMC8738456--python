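# energy_keV  mu_over_rho_cm2_g
1 1.17481e+06
1.09396 829507
1.19674 585702
1.30919 413559
1.43219 292014
1.56676 206194
1.71397 145597
1.87501 102811
2.05118 72600
2.24391 51267.8
2.45474 36204.8
2.68538 25568.4
2.93769 18057.6
3.21371 12753.8
3.51566 9008.4
3.84599 6363.36
4.20735 4495.36
4.60266 3176.05
5.03511 2244.22
5.5082 1586.02
6.02574 1121.06
6.5919 792.584
7.21126 560.497
7.88881 396.493
8.63003 280.584
9.44089 198.65
10.3279 140.72
11.2983 99.7512
12.3599 70.7688
13.5212 50.2586
14.7916 35.7379
16.1814 25.4525
17.7018 18.1628
19.365 12.9927
21.1845 9.32282
23.1749 6.71531
25.3524 4.86048
27.7344 3.53924
30.3403 2.59654
33.191 1.92262
36.3095 1.43971
39.7211 1.0927
43.4532 0.842495
47.5359 0.661359
52.0023 0.529577
56.8883 0.433128
62.2334 0.362028
68.0807 0.309157
74.4774 0.269429
81.4751 0.239207
89.1303 0.21588
97.5048 0.197574
106.666 0.182939
116.688 0.171001
127.652 0.161054
139.646 0.152585
152.767 0.145223
167.12 0.138697
182.822 0.132807
200 0.127408
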