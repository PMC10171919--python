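age,sex,qx
0,male,0.005
1,male,0.000435
2,male,0.000439
3,male,0.000442
4,male,0.000447
5,male,0.000451
6,male,0.000456
7,male,0.000462
8,male,0.000468
9,male,0.000474
10,male,0.000482
11,male,0.00049
12,male,0.000499
13,male,0.000508
14,male,0.000519
15,male,0.000531
16,male,0.000544
17,male,0.000558
18,male,0.000574
19,male,0.000591
20,male,0.00061
21,male,0.00063
22,male,0.000653
23,male,0.000678
24,male,0.000705
25,male,0.000735
26,male,0.000768
27,male,0.000805
28,male,0.000844
29,male,0.000888
30,male,0.000936
31,male,0.000989
32,male,0.001047
33,male,0.001111
34,male,0.001181
35,male,0.001258
36,male,0.001343
37,male,0.001436
38,male,0.001538
39,male,0.00165
40,male,0.001773
41,male,0.001908
42,male,0.002056
43,male,0.00222
44,male,0.002399
45,male,0.002596
46,male,0.002812
47,male,0.003049
48,male,0.00331
49,male,0.003596
50,male,0.003911
51,male,0.004256
52,male,0.004635
53,male,0.005052
54,male,0.005509
55,male,0.006011
56,male,0.006562
57,male,0.007168
58,male,0.007832
59,male,0.008562
60,male,0.009363
61,male,0.010242
62,male,0.011206
63,male,0.012265
64,male,0.013427
65,male,0.014702
66,male,0.0161
67,male,0.017634
68,male,0.019317
69,male,0.021162
70,male,0.023184
71,male,0.025402
72,male,0.027832
73,male,0.030494
74,male,0.033411
75,male,0.036605
76,male,0.040101
77,male,0.043928
78,male,0.048114
79,male,0.052692
80,male,0.057695
81,male,0.063161
82,male,0.069129
83,male,0.075642
84,male,0.082744
85,male,0.090483
86,male,0.09891
87,male,0.108077
88,male,0.11804
89,male,0.128857
90,male,0.140587
91,male,0.153292
92,male,0.167032
93,male,0.181869
94,male,0.197864
95,male,0.215076
96,male,0.233559
97,male,0.253362
98,male,0.274527
99,male,0.297088
100,male,1.0
0,female,0.004
1,female,0.000263
2,female,0.000265
3,female,0.000266
4,female,0.000268
5,female,0.00027
6,female,0.000272
7,female,0.000275
8,female,0.000277
9,female,0.00028
10,female,0.000284
11,female,0.000287
12,female,0.000291
13,female,0.000296
14,female,0.000301
15,female,0.000306
16,female,0.000312
17,female,0.000319
18,female,0.000327
19,female,0.000335
20,female,0.000344
21,female,0.000354
22,female,0.000366
23,female,0.000378
24,female,0.000392
25,female,0.000407
26,female,0.000425
27,female,0.000444
28,female,0.000465
29,female,0.000488
30,female,0.000514
31,female,0.000542
32,female,0.000574
33,female,0.000609
34,female,0.000648
35,female,0.000691
36,female,0.000739
37,female,0.000792
38,female,0.000851
39,female,0.000916
40,female,0.000988
41,female,0.001068
42,female,0.001157
43,female,0.001255
44,female,0.001364
45,female,0.001485
46,female,0.001619
47,female,0.001768
48,female,0.001932
49,female,0.002114
50,female,0.002316
51,female,0.00254
52,female,0.002789
53,female,0.003064
54,female,0.003368
55,female,0.003706
56,female,0.00408
57,female,0.004495
58,female,0.004955
59,female,0.005464
60,female,0.006028
61,female,0.006652
62,female,0.007345
63,female,0.008111
64,female,0.00896
65,female,0.009901
66,female,0.010942
67,female,0.012095
68,female,0.013372
69,female,0.014785
70,female,0.01635
71,female,0.018081
72,female,0.019996
73,female,0.022114
74,female,0.024458
75,female,0.027048
76,female,0.029912
77,female,0.033077
78,female,0.036573
79,female,0.040434
80,female,0.044695
81,female,0.049396
82,female,0.054581
83,female,0.060295
84,female,0.066588
85,female,0.073515
86,female,0.081134
87,female,0.089506
88,female,0.098697
89,female,0.108777
90,female,0.119818
91,female,0.131898
92,female,0.145095
93,female,0.159489
94,female,0.175162
95,female,0.192194
96,female,0.210663
97,female,0.230642
98,female,0.252199
99,female,0.27539
100,female,1.0
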