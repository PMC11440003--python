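item,gender,infant,kindergarten,primary,junior_high,non_autism,mild_moderate
1,0,-0.337,0,0,0,0,0
2,0,0,-0.018,-0.318,0,0,0
3,0,0,0,0,0,0,0
4,0,-0.957,0,0.18,0,0,0
5,0,0,0.313,0,0,0,0
6,0,-0.058,0,0.192,0,0,0
7,0,0.045,0,0,0,0,0
8,0,0.968,-0.137,-0.082,0,0,0
9,0,0,0,0,0,0,0
10,0,0,0,0,0,0,0
11,0,0.926,0,-0.019,0,0,0
12,0,0,0,0,0,0,0
13,0,0,0,0,0,0,0
14,0,0,0,0,0,0,0
15,0,-0.478,0,0.185,0,0,0
16,0,0,0.15,0,0,0,0
17,0,-0.05,0.108,0.059,0,0,0
18,0,-0.867,0,0.107,0,0,0
19,0,0.929,0,-0.015,0,0,0
20,0,-0.786,0,0.026,0,0,0
21,0,0,0,0,0,0,0
22,0,0,0,0,0,0,0
23,0,0,0,0,0,0,0
24,0,0.374,0,0,0,0,0
25,0.022,-0.199,0,0,0,0,0
26,0,0,0,-0.013,0,0,0
27,0,0,0,0,0,0,0
28,0,0,0,0,0,0,0
29,0,-1.321,0,0.175,0,0,0
30,0,-0.089,0.117,0,0,0,0
31,-0.087,0,0,0,0,0,0
32,0,1.066,0,-0.134,-0.034,0,0
33,0,0,0.123,0,0,0,0
34,0,0,0,0,0,0,0
35,0,0,0,0,0,0,0
36,0,-0.357,0,0.066,0,0,0
37,0,-1.201,0,0.177,0.032,0,0
38,0,0,0,0,0,0,0
39,0,0.12,0,-0.252,0,0,0
40,0,0,0,0,0,0,0
41,0,-0.807,0,0.163,0,0,0
42,0,-0.291,0,0,0,0,0
43,0,0.15,0,0,0,0,0
44,0,0.302,0,0,0,0,0
45,0,0.166,-1.262,0,0,0,0
46,0,0.212,0,0,0,0,0
47,0,0,0,0,0,0,0
48,0,0,-1.002,-0.613,0,0,0
49,0,0,0.126,0.101,0,0,0
50,0,0,0,0,0,0,0
51,0,0,0,0,0,0,0
52,0,0,0,0,0,0,0
53,0,0,-0.143,0,0,0,0
54,-0.021,0,0,0,0,0,0
55,0,-1.15,0,0,0,0,0
56,0,-0.687,-0.221,0,0,0,0
57,0,0.142,0,-0.161,0,0,0
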