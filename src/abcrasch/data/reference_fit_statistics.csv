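item,total_score,total_count,measure,se,infit_mnsq,infit_zstd,outfit_mnsq,outfit_zstd,corr
3,1405,3319,-1.16,0.04,0.86,-9.9,0.82,-8.34,0.51
4,1022,3319,-0.58,0.04,0.92,-4.61,0.83,-5.41,0.43
5,480,3319,0.51,0.05,0.89,-3.4,0.71,-5.41,0.38
6,1957,3319,-1.96,0.04,0.95,-3.41,0.93,-3.16,0.45
7,1181,3319,-0.83,0.04,0.83,-9.9,0.77,-8.91,0.53
8,690,3319,0.02,0.05,1.34,9.9,1.95,9.9,-0.09
10,3009,3319,-4.22,0.06,0.88,-2.59,0.6,-6.08,0.46
11,885,3319,-0.34,0.04,1.25,9.9,1.5,9.9,0.07
15,1764,3319,-1.68,0.04,0.82,-9.9,0.79,-9.9,0.56
16,1223,3319,-0.89,0.04,0.89,-7.88,0.84,-6.24,0.47
17,1380,3319,-1.12,0.04,0.86,-9.9,0.83,-7.83,0.51
18,2267,3319,-2.45,0.04,0.92,-4.13,0.87,-4.93,0.48
19,296,3319,1.1,0.06,1.13,2.65,1.82,8.19,0.01
20,887,3319,-0.35,0.04,0.87,-7.04,0.77,-6.62,0.46
23,2228,3319,-2.38,0.04,1.16,8.4,1.24,8.66,0.25
29,2192,3319,-2.32,0.04,0.92,-4.96,0.85,-6.3,0.49
31,831,3319,-0.25,0.04,1.19,8.81,1.47,9.9,0.11
32,575,3319,0.27,0.05,1.24,7.74,1.78,9.9,0.0
33,1156,3319,-0.79,0.04,0.83,-9.9,0.76,-9.21,0.52
36,1696,3319,-1.58,0.04,1.05,3.83,1.06,2.86,0.35
37,1521,3319,-1.33,0.04,0.93,-5.14,0.91,-4.53,0.45
38,3021,3319,-4.27,0.07,0.89,-2.27,0.61,-5.8,0.45
45,1380,3319,-1.12,0.04,1.14,9.75,1.19,7.75,0.24
48,833,3319,-0.25,0.04,1.31,9.9,1.6,9.9,0.0
49,2031,3319,-2.07,0.04,0.86,-9.16,0.81,-9.05,0.53
50,2110,3319,-2.19,0.04,0.83,-9.9,0.76,-9.9,0.57
52,1097,3319,-0.7,0.04,0.91,-5.67,0.92,-2.69,0.43
53,445,3319,0.6,0.05,1.08,2.29,1.32,4.56,0.15
54,520,3319,0.41,0.05,1.08,2.56,1.35,5.46,0.16
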