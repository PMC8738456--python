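# energy_keV  mu_over_rho_cm2_g
1 649963
1.09396 458934
1.19674 324053
1.30919 228817
1.43219 161573
1.56676 114092
1.71397 80566.5
1.87501 56893.7
2.05118 40178
2.24391 28374.5
2.45474 20039.5
2.68538 14153.7
2.93769 9997.28
3.21371 7061.97
3.51566 4988.94
3.84599 3524.83
4.20735 2490.71
4.60266 1760.25
5.03511 1244.25
5.5082 879.695
6.02574 622.118
6.5919 440.099
7.21126 311.453
7.88881 220.514
8.63003 156.215
9.44089 110.74
10.3279 78.5682
11.2983 55.8
12.3599 39.6797
13.5212 28.2604
14.7916 20.1664
16.1814 14.4254
17.7018 10.3498
19.365 7.45374
21.1845 5.3934
23.1749 3.92558
25.3524 2.87817
27.7344 2.1293
30.3403 1.59263
33.191 1.20698
36.3095 0.928926
39.7211 0.727662
43.4532 0.581286
47.5359 0.474222
52.0023 0.395373
56.8883 0.336825
62.2334 0.292921
68.0807 0.259611
74.4774 0.233992
81.4751 0.213973
89.1303 0.19805
97.5048 0.185132
106.666 0.174432
116.688 0.165375
127.652 0.157544
139.646 0.150633
152.767 0.14442
167.12 0.13874
182.822 0.133474
200 0.128532
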