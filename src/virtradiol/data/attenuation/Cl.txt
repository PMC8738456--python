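# energy_keV  mu_over_rho_cm2_g
1 776839
1.09396 548516
1.19674 387304
1.30919 273476
1.43219 193105
1.56676 136356
1.71397 96286.6
1.87501 67993.3
2.05118 48015.2
2.24391 33908.3
2.45474 23947
2.68538 16912.8
2.93769 11945.6
3.21371 8437.71
3.51566 5960.43
3.84599 4210.87
4.20735 2975.19
4.60266 2102.4
5.03511 1485.89
5.5082 1050.36
6.02574 742.664
6.5919 525.25
7.21126 371.607
7.88881 263.012
8.63003 186.243
9.44089 131.959
10.3279 93.5648
11.2983 66.4003
12.3599 47.1737
13.5212 33.5593
14.7916 23.9139
16.1814 17.076
17.7018 12.225
19.365 8.78041
21.1845 6.33203
23.1749 4.5896
25.3524 3.34776
27.7344 2.46117
30.3403 1.8269
33.191 1.37203
36.3095 1.04486
39.7211 0.808719
43.4532 0.637553
47.5359 0.512856
52.0023 0.421454
56.8883 0.353963
62.2334 0.303684
68.0807 0.265829
74.4774 0.236971
81.4751 0.214647
89.1303 0.197087
97.5048 0.183014
106.666 0.171505
116.688 0.16189
127.652 0.153683
139.646 0.146529
152.767 0.14017
167.12 0.134415
182.822 0.129125
200 0.1242
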