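# energy_keV  mu_over_rho_cm2_g
1 4.05468e+07
1.09396 2.86281e+07
1.19674 2.02129e+07
1.30919 1.42714e+07
1.43219 1.00764e+07
1.56676 7.11447e+06
1.71397 5.02322e+06
1.87501 3.54668e+06
2.05118 2.50417e+06
2.24391 1.7681e+06
2.45474 1.24839e+06
2.68538 881447
2.93769 622364
3.21371 439435
3.51566 310276
3.84599 219082
4.20735 154692
4.60266 109228
5.03511 77127.3
5.5082 54461.4
6.02574 38457.2
6.5919 27156.7
7.21126 19177.3
7.88881 13543
8.63003 9564.36
9.44089 6754.9
10.3279 4770.97
11.2983 3369.95
12.3599 2380.53
13.5212 1681.77
14.7916 1188.26
16.1814 839.678
17.7018 593.455
19.365 419.519
21.1845 296.634
23.1749 209.808
25.3524 148.45
27.7344 105.084
30.3403 74.427
33.191 52.7503
36.3095 37.419
39.7211 26.572
43.4532 18.8948
47.5359 13.4585
52.0023 9.60689
56.8883 6.87621
62.2334 4.93867
68.0807 3.56255
74.4774 2.58402
81.4751 1.8872
89.1303 1.39011
97.5048 1.03472
106.666 0.779951
116.688 0.596713
127.652 0.464378
139.646 0.368316
152.767 0.298147
167.12 0.246496
182.822 0.208119
200 0.179283
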