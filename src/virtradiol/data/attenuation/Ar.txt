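# energy_keV  mu_over_rho_cm2_g
1 896656
1.09396 633113
1.19674 447034
1.30919 315649
1.43219 222882
1.56676 157380
1.71397 111131
1.87501 78474.3
2.05118 55415.5
2.24391 39133.5
2.45474 27636.3
2.68538 19517.8
2.93769 13784.9
3.21371 9736.44
3.51566 6877.46
3.84599 4858.39
4.20735 3432.41
4.60266 2425.26
5.03511 1713.87
5.5082 1211.36
6.02574 856.354
6.5919 605.537
7.21126 428.307
7.88881 303.055
8.63003 214.523
9.44089 151.933
10.3279 107.672
11.2983 76.3644
12.3599 54.2113
13.5212 38.5297
14.7916 27.4239
16.1814 19.5544
17.7018 13.9744
19.365 10.0148
21.1845 7.20239
23.1749 5.20264
25.3524 3.77888
27.7344 2.76366
30.3403 2.03842
33.191 1.51919
36.3095 1.14649
39.7211 0.878128
43.4532 0.684162
47.5359 0.543333
52.0023 0.440521
56.8883 0.364966
62.2334 0.308996
68.0807 0.267136
74.4774 0.235469
81.4751 0.21119
89.1303 0.192282
97.5048 0.177295
106.666 0.165182
116.688 0.155187
127.652 0.14676
139.646 0.139502
152.767 0.133122
167.12 0.127408
182.822 0.122203
200 0.117394
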