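age,qx
0,0.0005080411185640621
1,0.0005089906523216836
2,0.0005100505949670042
3,0.0005112337843701242
4,0.0005125545510996643
5,0.000514028891974494
6,0.0005156746637926535
7,0.0005175117995813716
8,0.0005195625499860856
9,0.0005218517527206812
10,0.000524407133339122
11,0.000527259640968003
12,0.0005304438230639974
13,0.0005339982437276847
14,0.0005379659506370427
15,0.000542394996245088
16,0.0005473390195475103
17,0.000552857895452119
18,0.0005590184596020453
19,0.0005658953174108028
20,0.0005735717470859436
21,0.000582140707548362
22,0.0005917059634189537
23,0.0006023833406521018
24,0.0006143021279658711
25,0.0006276066409746095
26,0.0006424579678757647
27,0.0006590359177264249
28,0.0006775411947683718
29,0.0006981978249629428
30,0.0007212558639133615
31,0.000746994418702851
32,0.0007757250199172949
33,0.0008077953842765551
34,0.0008435936129299604
35,0.0008835528756210298
36,0.0009281566366490246
37,0.0009779444849232766
38,0.0010335186374749172
39,0.0010955511936391327
40,0.001164792225832656
41,0.0012420788025075957
42,0.0013283450495576998
43,0.001424633368295125
44,0.0015321069412018717
45,0.0016520636711131464
46,0.0017859517154252824
47,0.0019353867944633674
48,0.00210217147242564
49,0.0022883166304584757
50,0.0024960653745501604
51,0.0027279196461597044
52,0.0029866698309380935
53,0.003275427690626609
54,0.003597662975273752
55,0.003957244107310909
56,0.0043584833656905575
57,0.00480618703707858
58,0.005305711041736605
59,0.0058630225838035566
60,0.0064847684185938
61,0.007178350372381903
62,0.007952008791773935
63,0.008814914638555882
64,0.009777270979762553
65,0.010850424648856993
66,0.01204698886879807
67,0.013380977626840318
68,0.014867952568386467
69,0.01652518312581719
70,0.01837182050886721
71,0.02042908604450344
72,0.022720474152482906
73,0.025271969960767082
74,0.02811228118204534
75,0.03127308336380741
76,0.03478927695988021
77,0.03869925381583572
78,0.04304516957300053
79,0.04787321712847248
80,0.05323389458788219
81,0.05918225905421182
82,0.06577815504601348
83,0.07308640326625393
84,0.0811769317856138
85,0.09012482740730954
86,0.10001028000933954
87,0.11091838701257972
88,0.12293877885036175
89,0.13616501954749183
90,0.15069372949885607
91,0.166623370673059
92,0.18405262837087133
93,0.2030783192334974
94,0.2237927536589973
95,0.24628048379801315
96,0.2706143779838356
97,0.2968509814219812
98,0.3250251542894529
99,0.3551440254493279
100,1.0
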