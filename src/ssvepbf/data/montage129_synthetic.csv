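id,name,x,y,z
1,,-0.175386,0.015392,0.984379
2,,0.165060,0.126548,0.978131
3,,-0.041014,-0.231865,0.971883
4,,-0.139497,0.219294,0.965635
5,,0.272423,-0.073233,0.959387
6,,-0.268484,-0.139440,0.953138
7,,0.110306,0.302045,0.946890
8,,0.498097,0.862730,-0.087156
9,,0.129500,-0.313723,0.940642
10,,-0.322660,0.150992,0.934394
11,,-0.194262,-0.335212,0.921897
12,,-0.086313,0.392603,0.915649
13,,0.340249,-0.239208,0.909401
14,,0.284990,0.338146,0.896905
15,,0.018786,-0.454289,0.890656
16,,-0.329211,0.330821,0.884408
17,,-0.375955,-0.313732,0.871912
18,,0.066757,0.496156,0.865663
19,,0.292007,-0.419687,0.859415
20,,0.461347,0.264362,0.846919
21,,-0.164595,-0.515928,0.840671
22,,-0.231154,0.500307,0.834422
23,,0.269139,0.512088,0.815678
24,,0.149676,-0.567821,0.809430
25,,-0.498097,0.862730,-0.087156
26,,-0.501088,0.322196,0.803181
27,,-0.374866,-0.484038,0.790685
28,,-0.051208,0.618091,0.784437
29,,-0.492404,0.086824,0.866025
30,,-0.521869,-0.092020,0.848048
31,,0.461015,-0.426483,0.778188
32,,0.476395,0.432161,0.765692
33,,-0.397678,0.523974,0.753196
34,,-0.568618,-0.357824,0.740699
35,,-0.672499,-0.218508,0.707107
36,C3,-0.707107,-0.000000,0.707107
37,,0.179379,0.654527,0.734451
38,,0.312917,-0.609757,0.728203
39,,-0.648789,0.240530,0.721955
40,,0.646856,0.263327,0.715706
41,,-0.301815,-0.636849,0.709458
42,,-0.209474,0.679424,0.703210
43,,0.422200,0.594352,0.684465
44,,-0.563948,0.480021,0.671969
45,,-0.535428,-0.527649,0.659472
46,,0.038664,0.756177,0.653224
47,,-0.784886,-0.453154,0.422618
48,,0.485686,-0.587819,0.646976
49,,0.636620,0.438350,0.634480
50,,-0.174463,-0.758214,0.628231
51,,-0.385989,0.681285,0.621983
52,,-0.640342,-0.763129,0.087156
53,,0.311493,0.734218,0.603239
54,,0.267837,-0.756218,0.596990
55,,-0.712385,0.378856,0.590742
56,,0.785597,0.202987,0.584494
57,,-0.444592,-0.684083,0.578246
58,,-0.134986,0.809072,0.571997
59,,0.649459,-0.508065,0.565749
60,,-0.826324,-0.064402,0.559501
61,,0.568658,0.608719,0.553253
62,Pz,0.000000,-0.707107,0.707107
63,,-0.008167,-0.837090,0.547005
64,,-0.562130,0.625774,0.540756
65,,-0.299838,-0.922806,0.241922
66,,-0.462339,-0.869534,0.173648
67,,0.841166,-0.082100,0.534508
68,,-0.678841,-0.510016,0.528260
69,,-0.469186,-0.882410,-0.034899
70,O1,-0.275469,-0.960676,0.034899
71,,0.156754,0.838410,0.522012
72,,0.452757,-0.727323,0.515764
73,,-0.828742,0.231476,0.509515
74,,0.770721,0.390783,0.503267
75,Oz,0.000000,-1.000000,0.000000
76,,-0.305606,-0.812143,0.497019
77,,-0.324572,0.808577,0.490771
78,,0.788662,-0.378484,0.484523
79,,-0.840481,-0.254646,0.478274
80,,0.492404,0.086824,0.866025
81,,0.449454,0.758408,0.472026
82,,0.181564,-0.866075,0.465778
83,O2,0.275469,-0.960676,0.034899
84,,0.469186,-0.882410,-0.034899
85,,-0.721554,0.517873,0.459530
86,,0.885052,0.105920,0.453281
87,,0.672499,-0.218508,0.707107
88,,-0.583115,-0.678335,0.447033
89,,0.462339,-0.869534,0.173648
90,,0.299838,-0.922806,0.241922
91,,-0.028336,0.897165,0.440785
92,,0.629044,-0.644578,0.434537
93,,-0.902227,0.050545,0.428289
94,,0.701689,0.574034,0.422040
95,,-0.130062,-0.900112,0.415792
96,,-0.513707,0.753909,0.409544
97,,0.890755,-0.209541,0.403296
98,,0.288307,0.874159,0.390799
99,,0.378976,-0.841723,0.384551
100,,-0.850389,0.365684,0.378303
101,,0.876455,0.305619,0.372055
102,,-0.441003,-0.819574,0.365807
103,,-0.229029,0.904579,0.359558
104,C4,0.707107,0.000000,0.707107
105,,0.521869,-0.092020,0.848048
106,,0.781906,-0.513610,0.353310
107,,-0.925798,-0.149823,0.347062
108,,0.582869,0.737638,0.340814
109,,0.068641,-0.939869,0.334565
110,,-0.687083,0.648171,0.328317
111,,0.946615,-0.013855,0.322069
112,,-0.708934,-0.630611,0.315821
113,,0.096984,0.945917,0.309573
114,,0.568645,-0.764616,0.303324
115,,-0.937723,0.180061,0.297076
116,,0.814713,0.501659,0.290828
117,,-0.430173,0.858768,0.278332
118,,0.898957,-0.343289,0.272083
119,,-0.896374,-0.354748,0.265835
120,,0.422073,0.868602,0.259587
121,,-0.831183,0.498077,0.247090
122,,0.950875,0.194504,0.240842
123,,-0.110972,0.967235,0.228346
124,,0.736276,-0.639195,0.222098
125,,-0.976079,-0.026062,0.215849
126,,0.321394,0.883022,-0.342020
127,,-0.321394,0.883022,-0.342020
128,,0.703103,0.679495,0.209601
129,Cz,0.000000,0.000000,1.000000
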