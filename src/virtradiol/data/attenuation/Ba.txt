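# energy_keV  mu_over_rho_cm2_g
1 4.82693e+07
1.09396 3.40806e+07
1.19674 2.40626e+07
1.30919 1.69895e+07
1.43219 1.19955e+07
1.56676 8.46945e+06
1.71397 5.9799e+06
1.87501 4.22214e+06
2.05118 2.98108e+06
2.24391 2.10482e+06
2.45474 1.48613e+06
2.68538 1.04931e+06
2.93769 740883
3.21371 523117
3.51566 369360
3.84599 260799
4.20735 184147
4.60266 130025
5.03511 91811.3
5.5082 64829.3
6.02574 45777.7
6.5919 32325.6
7.21126 22827
7.88881 16120
8.63003 11384
9.44089 8039.77
10.3279 5678.25
11.2983 4010.61
12.3599 2832.94
13.5212 2001.25
14.7916 1413.87
16.1814 999.011
17.7018 705.985
19.365 498.997
21.1845 352.772
23.1749 249.462
25.3524 176.464
27.7344 124.875
30.3403 88.4112
33.191 62.6324
36.3095 44.4032
39.7211 31.5089
43.4532 22.3851
47.5359 15.9266
52.0023 11.3524
56.8883 8.11097
62.2334 5.81229
68.0807 4.18075
74.4774 3.02153
81.4751 2.19683
89.1303 1.60921
97.5048 1.1897
106.666 0.889504
116.688 0.674056
127.652 0.51887
139.646 0.406589
152.767 0.3249
167.12 0.265062
182.822 0.220863
200 0.187884
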