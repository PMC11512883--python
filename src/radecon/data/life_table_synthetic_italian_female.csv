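age,q
0,1e-05
1,1.1051709180756478e-05
2,1.22140275816017e-05
3,1.3498588075760033e-05
4,1.4918246976412705e-05
5,1.6487212707001284e-05
6,1.822118800390509e-05
7,2.0137527074704767e-05
8,2.225540928492468e-05
9,2.45960311115695e-05
10,2.7182818284590452e-05
11,3.0041660239464337e-05
12,3.320116922736548e-05
13,3.669296667619245e-05
14,4.0551999668446755e-05
15,4.4816890703380646e-05
16,4.9530324243951155e-05
17,5.4739473917272015e-05
18,6.049647464412947e-05
19,6.685894442279271e-05
20,7.389056098930651e-05
21,8.16616991256765e-05
22,9.025013499434122e-05
23,9.974182454814724e-05
24,0.00011023176380641606
25,0.00012182493960703475
26,0.00013463738035001692
27,0.0001487973172487284
28,0.00016444646771097057
29,0.00018174145369443068
30,0.0002008553692318767
31,0.0002219795128144164
32,0.00024532530197109354
33,0.00027112638920657897
34,0.00029964100047397027
35,0.00033115451958692314
36,0.0003659823444367799
37,0.00040447304360067404
38,0.0004470118449330084
39,0.0004940244910553019
40,0.0005459815003314424
41,0.0006034028759736201
42,0.0006668633104092515
43,0.0007369979369959579
44,0.0008145086866496815
45,0.0009001713130052182
46,0.0009948431564193387
47,0.0010994717245212354
48,0.0012151041751873497
49,0.0013428977968493554
50,0.0014841315910257662
51,0.0016402190729990186
52,0.001812722418751512
53,0.0020033680997479184
54,0.0022140641620418716
55,0.002446919322642204
56,0.002704264074261528
57,0.002988674009670603
58,0.0033029955990964894
59,0.003650374678653289
60,0.004034287934927352
61,0.004458577700825172
62,0.004927490410932564
63,0.005445719101259295
64,0.006018450378720823
65,0.006651416330443619
66,0.007350951892419733
67,0.008124058251675434
68,0.008978472916504185
69,0.009922747156050264
70,0.010966331584284585
71,0.012119670744925776
72,0.013394307643944182
73,0.014802999275845465
74,0.01635984429995927
75,0.018080424144560632
76,0.01998195895104119
77,0.022083479918872093
78,0.02440601977624501
79,0.0269728232826851
80,0.029809579870417286
81,0.03294468075283841
82,0.036409503073323586
83,0.040238723938223135
84,0.044470667476998585
85,0.04914768840299135
86,0.054316595913629785
87,0.06002912217261029
88,0.0663424400627789
89,0.07331973539155996
90,0.08103083927575384
91,0.08955292703482509
92,0.09897129058743928
93,0.10938019208165192
94,0.1208838073021699
95,0.13359726829661872
96,0.14764781565577295
97,0.16317607198015452
98,0.18033744927828527
99,0.199303704382303
100,0.2202646579480672
101,0.24343009424408424
102,0.2690318607429759
103,0.2973261885289144
104,0.32859625674443327
105,0.3631550267424664
106,0.4013483743087585
107,0.4435585513029792
108,0.49020801136381753
109,0.5417636379669876
110,1.0
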