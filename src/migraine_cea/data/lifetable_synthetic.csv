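age,sex,qx
41,F,0.0008
42,F,0.000872
43,F,0.0009504800000000002
44,F,0.0010360232000000001
45,F,0.0011292652880000005
46,F,0.0012308991639200005
47,F,0.0013416800886728005
48,F,0.0014624312966533526
49,F,0.0015940501133521548
50,F,0.0017375146235538489
51,F,0.0018938909396736955
52,F,0.002064341124244328
53,F,0.002250131825426318
54,F,0.0024526436897146864
55,F,0.0026733816217890086
56,F,0.002913985967750019
57,F,0.0031762447048475214
58,F,0.0034621067282837987
59,F,0.003773696333829341
60,F,0.004113329003873982
61,F,0.00448352861422264
62,F,0.004887046189502678
63,F,0.0053268803465579195
64,F,0.005806299577748133
65,F,0.006328866539745465
66,F,0.0068984645283225576
67,F,0.007519326335871588
68,F,0.008196065706100032
69,F,0.008933711619649036
70,F,0.00973774566541745
71,F,0.010614142775305022
72,F,0.011569415625082473
73,F,0.012610663031339897
74,F,0.013745622704160488
75,F,0.014982728747534932
76,F,0.01633117433481308
77,F,0.017800980024946258
78,F,0.01940306822719142
79,F,0.021149344367638653
80,F,0.023052785360726132
81,F,0.025127536043191484
82,F,0.02738901428707872
83,F,0.029854025572915808
84,F,0.03254088787447824
85,F,0.03546956778318128
86,F,0.0386618288836676
87,F,0.04214139348319768
88,F,0.04593411889668548
89,F,0.050068189597387174
90,F,0.05457432666115202
91,F,0.05948601606065571
92,F,0.06483975750611473
93,F,0.07067533568166506
94,F,0.07703611589301491
95,F,0.08396936632338627
96,F,0.09152660929249104
97,F,0.09976400412881524
98,F,0.10874276450040862
99,F,0.11852961330544541
100,F,0.1291972785029355
101,F,0.14082503356819973
41,M,0.00144
42,M,0.0015696000000000002
43,M,0.0017108640000000003
44,M,0.0018648417600000003
45,M,0.002032677518400001
46,M,0.002215618495056001
47,M,0.002415024159611041
48,M,0.002632376333976035
49,M,0.002869290204033879
50,M,0.003127526322396928
51,M,0.003409003691412652
52,M,0.0037158140236397902
53,M,0.004050237285767372
54,M,0.0044147586414864355
55,M,0.004812086919220216
56,M,0.005245174741950034
57,M,0.005717240468725539
58,M,0.006231792110910838
59,M,0.006792653400892814
60,M,0.007403992206973167
61,M,0.008070351505600752
62,M,0.008796683141104822
63,M,0.009588384623804255
64,M,0.01045133923994664
65,M,0.011391959771541837
66,M,0.012417236150980605
67,M,0.013534787404568859
68,M,0.014752918270980056
69,M,0.016080680915368264
70,M,0.01752794219775141
71,M,0.01910545699554904
72,M,0.020824948125148453
73,M,0.022699193456411814
74,M,0.02474212086748888
75,M,0.026968911745562877
76,M,0.029396113802663545
77,M,0.03204176404490326
78,M,0.03492552280894456
79,M,0.03806881986174958
80,M,0.041495013649307036
81,M,0.045229564877744675
82,M,0.0493002257167417
83,M,0.05373724603124846
84,M,0.058573598174060826
85,M,0.0638452220097263
86,M,0.06959129199060168
87,M,0.07585450826975583
88,M,0.08268141401403387
89,M,0.09012274127529692
90,M,0.09823378799007364
91,M,0.10707482890918028
92,M,0.11671156351100652
93,M,0.12721560422699713
94,M,0.13866500860742684
95,M,0.1511448593820953
96,M,0.16474789672648388
97,M,0.17957520743186745
98,M,0.19573697610073554
99,M,0.21335330394980173
100,M,0.2325551013052839
101,M,0.25348506042275953
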