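serial,icga,omag,ssada
1,21.49,18.37,18.92
2,20.32,14.72,15.94
3,18.19,23.03,22.35
4,21.92,23.85,22.11
5,22.18,20.08,23.15
6,28.11,30.07,28.93
7,32.53,39.71,26.31
8,17.04,17.69,18.80
9,37.00,36.74,29.66
10,17.96,16.24,23.49
11,18.82,19.26,19.84
12,23.42,27.63,25.51
13,26.50,22.41,23.23
14,24.79,24.24,27.31
15,27.21,29.83,21.06
16,30.19,20.91,29.01
17,6.72,6.46,6.87
18,5.44,5.61,6.20
19,7.62,5.84,8.84
20,7.93,8.43,10.45
21,7.73,6.66,9.41
22,11.41,8.44,12.96
23,8.69,7.14,11.97
24,11.81,9.55,10.01
25,8.39,10.26,11.95
26,14.87,14.40,16.65
27,7.54,8.34,10.36
28,10.84,8.82,12.76
29,8.68,11.55,12.09
30,6.80,8.25,10.50
31,10.20,9.03,13.96
32,6.32,5.71,6.41
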