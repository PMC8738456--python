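# energy_keV  mu_over_rho_cm2_g
1 3.48095e+06
1.09396 2.45777e+06
1.19674 1.73535e+06
1.30919 1.22528e+06
1.43219 865139
1.56676 610857
1.71397 431317
1.87501 304549
2.05118 215042
2.24391 151843
2.45474 107220
2.68538 75711.7
2.93769 53463.9
3.21371 37754.6
3.51566 26662
3.84599 18829.2
4.20735 13298.2
4.60266 9392.34
5.03511 6634.14
5.5082 4686.27
6.02574 3310.63
6.5919 2339.06
7.21126 1652.82
7.88881 1168.1
8.63003 825.686
9.44089 583.777
10.3279 412.854
11.2983 292.071
12.3599 206.706
13.5212 146.362
14.7916 103.695
16.1814 73.5204
17.7018 52.1731
19.365 37.0655
21.1845 26.369
23.1749 18.7919
25.3524 13.4212
27.7344 9.61166
30.3403 6.90715
33.191 4.98516
36.3095 3.6176
39.7211 2.64311
43.4532 1.94748
47.5359 1.44986
52.0023 1.09295
56.8883 0.836173
62.2334 0.650722
68.0807 0.51616
74.4774 0.417965
81.4751 0.345808
89.1303 0.292336
97.5048 0.252303
106.666 0.221965
116.688 0.198645
127.652 0.180421
139.646 0.165917
152.767 0.154139
167.12 0.144374
182.822 0.136103
200 0.128953
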