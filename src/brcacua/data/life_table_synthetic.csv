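# synthetic Gompertz-Makeham female life table (age, qx)
age,qx
0,0.00020408
1,0.00020459
2,0.00020517
3,0.00020582
4,0.00020655
5,0.00020737
6,0.00020830
7,0.00020934
8,0.00021052
9,0.00021184
10,0.00021332
11,0.00021499
12,0.00021687
13,0.00021899
14,0.00022137
15,0.00022405
16,0.00022706
17,0.00023045
18,0.00023427
19,0.00023856
20,0.00024339
21,0.00024883
22,0.00025495
23,0.00026183
24,0.00026958
25,0.00027830
26,0.00028810
27,0.00029914
28,0.00031156
29,0.00032553
30,0.00034126
31,0.00035895
32,0.00037886
33,0.00040126
34,0.00042646
35,0.00045483
36,0.00048674
37,0.00052265
38,0.00056305
39,0.00060852
40,0.00065967
41,0.00071723
42,0.00078199
43,0.00085486
44,0.00093686
45,0.00102911
46,0.00113290
47,0.00124968
48,0.00138107
49,0.00152890
50,0.00169522
51,0.00188233
52,0.00209283
53,0.00232965
54,0.00259606
55,0.00289575
56,0.00323286
57,0.00361206
58,0.00403858
59,0.00451831
60,0.00505784
61,0.00566459
62,0.00634689
63,0.00711409
64,0.00797666
65,0.00894637
66,0.01003640
67,0.01126152
68,0.01263826
69,0.01418514
70,0.01592286
71,0.01787455
72,0.02006605
73,0.02252618
74,0.02528705
75,0.02838437
76,0.03185785
77,0.03575151
78,0.04011411
79,0.04499951
80,0.05046704
81,0.05658194
82,0.06341561
83,0.07104600
84,0.07955773
85,0.08904230
86,0.09959794
87,0.11132943
88,0.12434756
89,0.13876825
90,0.15471127
91,0.17229844
92,0.19165115
93,0.21288716
94,0.23611651
95,0.26143650
96,0.28892556
97,0.31863600
98,0.35058580
99,0.38474930
100,0.42104739
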