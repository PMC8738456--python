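# energy_keV  mu_over_rho_cm2_g
1 297199
1.09396 209857
1.19674 148186
1.30919 104641
1.43219 73893.5
1.56676 52182.3
1.71397 36851.6
1.87501 26026
2.05118 18381.5
2.24391 12983.1
2.45474 9170.82
2.68538 6478.49
2.93769 4577.01
3.21371 3234.02
3.51566 2285.41
3.84599 1615.32
4.20735 1141.93
4.60266 807.467
5.03511 571.132
5.5082 404.108
6.02574 286.049
6.5919 202.583
7.21126 143.559
7.88881 101.807
8.63003 72.2641
9.44089 51.3509
10.3279 36.5398
11.2983 26.0445
12.3599 18.6026
13.5212 13.3216
14.7916 9.57066
16.1814 6.90362
17.7018 5.00485
19.365 3.65103
21.1845 2.68405
23.1749 1.99192
25.3524 1.49531
27.7344 1.13795
30.3403 0.879886
33.191 0.692771
36.3095 0.556433
39.7211 0.45651
43.4532 0.382767
47.5359 0.327892
52.0023 0.286656
56.8883 0.255306
62.2334 0.231149
68.0807 0.212241
74.4774 0.19718
81.4751 0.184948
89.1303 0.174806
97.5048 0.166213
106.666 0.158775
116.688 0.152204
127.652 0.146285
139.646 0.140863
152.767 0.135822
167.12 0.131077
182.822 0.126567
200 0.122246
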