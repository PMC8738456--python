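# energy_keV  mu_over_rho_cm2_g
1 1.88337e+06
1.09396 1.32979e+06
1.19674 938932
1.30919 662961
1.43219 468107
1.56676 330527
1.71397 233385
1.87501 164796
2.05118 116366
2.24391 82170.2
2.45474 58024.7
2.68538 40975.4
2.93769 28936.6
3.21371 20435.6
3.51566 14432.7
3.84599 10193.7
4.20735 7200.22
4.60266 5086.18
5.03511 3593.17
5.5082 2538.69
6.02574 1793.91
6.5919 1267.82
7.21126 896.182
7.88881 633.626
8.63003 448.112
9.44089 317.017
10.3279 224.363
11.2983 158.865
12.3599 112.554
13.5212 79.8006
14.7916 56.6287
16.1814 40.2292
17.7018 28.6179
19.365 20.3923
21.1845 14.5618
23.1749 10.426
25.3524 7.48973
27.7344 5.40298
30.3403 3.91816
33.191 2.86011
36.3095 2.10486
39.7211 1.56463
43.4532 1.17722
47.5359 0.898579
52.0023 0.697422
56.8883 0.551559
62.2334 0.445218
68.0807 0.367179
74.4774 0.309451
81.4751 0.266337
89.1303 0.233765
97.5048 0.208821
106.666 0.189416
116.688 0.174051
127.652 0.161644
139.646 0.151414
152.767 0.142798
167.12 0.135387
182.822 0.128882
200 0.123067
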