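plot,manual,cvi_tp,cvi_fp,cvi_fn,cvi_s,cvi_p,cvi_f,tin_tp,tin_fp,tin_fn,tin_s,tin_p,tin_f
1,16,16,0,0,1.00,1.00,1.00,11,0,5,0.69,1.00,0.81
2,21,16,0,5,0.76,1.00,0.86,10,1,10,0.50,0.91,0.65
3,9,5,0,4,0.56,1.00,0.71,4,1,4,0.50,0.80,0.62
4,22,11,2,9,0.55,0.85,0.67,6,2,14,0.30,0.75,0.43
5,20,15,1,4,0.79,0.94,0.86,14,1,5,0.74,0.93,0.82
6,28,22,0,6,0.79,1.00,0.88,19,2,7,0.73,0.90,0.81
7,30,25,0,5,0.83,1.00,0.91,16,0,14,0.53,1.00,0.70
8,17,11,1,5,0.69,0.92,0.79,11,1,5,0.69,0.92,0.79
9,26,16,0,10,0.62,1.00,0.76,13,2,11,0.54,0.87,0.67
10,25,18,0,7,0.72,1.00,0.84,18,0,7,0.72,1.00,0.84
11,25,13,0,12,0.52,1.00,0.68,11,0,14,0.44,1.00,0.61
12,24,19,1,4,0.83,0.95,0.88,8,1,15,0.35,0.89,0.50
13,24,14,0,10,0.58,1.00,0.74,12,0,12,0.50,1.00,0.67
14,17,15,0,2,0.88,1.00,0.94,13,0,4,0.76,1.00,0.87
15,28,23,0,5,0.82,1.00,0.90,16,0,12,0.57,1.00,0.73
16,10,8,0,2,0.80,1.00,0.89,9,0,1,0.90,1.00,0.95
17,20,13,0,7,0.65,1.00,0.79,11,0,9,0.55,1.00,0.71
18,31,23,0,8,0.74,1.00,0.85,25,0,6,0.81,1.00,0.89
19,29,27,0,2,0.93,1.00,0.96,22,0,7,0.76,1.00,0.86
20,23,18,0,5,0.78,1.00,0.88,16,0,7,0.70,1.00,0.82
21,21,11,0,10,0.52,1.00,0.69,10,1,10,0.50,0.91,0.65
22,15,12,0,3,0.80,1.00,0.89,11,0,4,0.73,1.00,0.85
23,18,14,1,3,0.82,0.93,0.88,10,1,7,0.59,0.91,0.71
24,18,15,0,3,0.83,1.00,0.91,11,1,6,0.65,0.92,0.76
25,26,17,0,9,0.65,1.00,0.79,13,3,10,0.57,0.81,0.67
26,18,13,0,5,0.72,1.00,0.84,11,3,4,0.73,0.79,0.76
27,29,20,0,9,0.69,1.00,0.82,18,1,10,0.64,0.95,0.77
28,33,22,0,11,0.67,1.00,0.80,17,0,16,0.52,1.00,0.68
29,10,7,1,2,0.78,0.88,0.82,5,1,4,0.56,0.83,0.67
30,27,22,1,4,0.85,0.96,0.90,21,1,5,0.81,0.95,0.88
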