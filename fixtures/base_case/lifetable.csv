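age,sex,all_cause_q,noncirc_fraction
35,male,0.0009334425832377085,0.8624999999999999
36,male,0.0010213488698940607,0.86
37,male,0.0011175336681294604,0.8574999999999999
38,male,0.0012227766008420084,0.855
39,male,0.0013379307113577964,0.8524999999999999
40,male,0.001463929377747119,0.85
41,male,0.0016017938782914686,0.8475
42,male,0.0017526416694229586,0.845
43,male,0.0019176954432327696,0.8425
44,male,0.002098293037963962,0.84
45,male,0.002295898281817848,0.8375
46,male,0.0025121128579680663,0.835
47,male,0.0027486892869538573,0.8325
48,male,0.0030075451316809248,0.83
49,male,0.0032907785401680677,0.8275
50,male,0.0036006852520208727,0.825
51,male,0.003939777206477852,0.8225
52,male,0.004310802902856019,0.82
53,male,0.004716769678426825,0.8175
54,male,0.005160968084295126,0.815
55,male,0.005646998556859075,0.8125
56,male,0.006178800601035635,0.8099999999999999
57,male,0.006760684721795488,0.8075
58,male,0.007397367362827336,0.8049999999999999
59,male,0.0080940091355259,0.8025
60,male,0.00885625664816748,0.7999999999999999
61,male,0.009690288274318167,0.7975
62,male,0.010602864231449077,0.7949999999999999
63,male,0.011601381375669387,0.7925
64,male,0.012693933156714018,0.79
65,male,0.01388937521914938,0.7875
66,male,0.01519739718152567,0.7849999999999999
67,male,0.01662860117527943,0.7825
68,male,0.018194587779981,0.78
69,male,0.019908050051472285,0.7775
70,male,0.02178287640503716,0.775
71,male,0.023834263187520657,0.7725
72,male,0.02607883785084688,0.77
73,male,0.028534793725314707,0.7675
74,male,0.03122203748507217,0.765
75,male,0.03416235050104607,0.7625
76,male,0.0373795653891684,0.76
77,male,0.04089975918490541,0.7575
78,male,0.04475146470985947,0.755
79,male,0.048965901843669474,0.7525
80,male,0.05357723057577668,0.75
81,male,0.05862282788815939,0.7474999999999999
82,male,0.06414359071330061,0.745
83,male,0.07018426742300587,0.7424999999999999
84,male,0.07679382053494238,0.74
85,male,0.08402582357680705,0.7374999999999999
86,male,0.0919388953248932,0.735
87,male,0.10059717493676341,0.7324999999999999
88,male,0.11007084182920082,0.73
89,male,0.12043668451529531,0.7275
90,male,0.13177872301135363,0.725
91,male,0.14418888985853515,0.7224999999999999
92,male,0.15776777527921215,0.72
93,male,0.17262544250789652,0.7175
94,male,0.18888231990537263,0.715
95,male,0.20667017708703941,0.7124999999999999
96,male,0.22613319297744072,0.71
97,male,0.24742912444806328,0.7075
98,male,0.27073058501076697,0.705
99,male,0.2962264439312485,0.7025
100,male,0.3241233571030154,0.7
101,male,0.3546474420903199,0.6975
102,male,0.3880461109170608,0.695
103,male,0.42459007545726757,0.6925
104,male,0.4645755416817969,0.69
105,male,0.5083266105466401,0.6875
106,male,0.5561979049831673,0.6849999999999999
107,male,0.6085774442832956,0.6825
108,male,0.6658897891778225,0.6799999999999999
109,male,0.7285994831002587,0.6775
110,male,0.797214817529212,0.6749999999999999
35,female,0.0005506186439894316,0.8624999999999999
36,female,0.000603678911651854,0.86
37,female,0.0006618523225671262,0.8574999999999999
38,female,0.0007256316038750829,0.855
39,female,0.0007955569642787232,0.8524999999999999
40,female,0.0008722206695965969,0.85
41,female,0.000956272059237484,0.8475
42,female,0.0010484230460867606,0.845
43,female,0.0011494541463883397,0.8425
44,female,0.0012602210906951094,0.84
45,female,0.0013816620718824363,0.8375
46,female,0.001514805691615201,0.835
47,female,0.0016607796725747082,0.8325
48,female,0.0018208204102378083,0.83
49,female,0.0019962834451114943,0.8275
50,female,0.002188654944122543,0.825
51,female,0.0023995642884092135,0.8225
52,female,0.0026307978741332487,0.82
53,female,0.0028843142432046923,0.8175
54,female,0.0031622606720762775,0.815
55,female,0.003466991359114071,0.8125
56,female,0.0038010873645908305,0.8099999999999999
57,female,0.0041673784721932665,0.8075
58,female,0.004568967157209599,0.8049999999999999
59,female,0.005009254864407197,0.8025
60,female,0.0054919708181732614,0.7999999999999999
61,female,0.006021203608939569,0.7975
62,female,0.006601435823427402,0.7949999999999999
63,female,0.007237582012029918,0.7925
64,female,0.0079350303149145,0.79
65,female,0.008699688099417121,0.7875
66,female,0.009538031995276058,0.7849999999999999
67,female,0.010457162751501973,0.7825
68,female,0.01146486537952061,0.78
69,female,0.01256967509199863,0.7775
70,female,0.01378094959585275,0.775
71,female,0.015108948351761813,0.7725
72,female,0.016564919471507587,0.77
73,female,0.018161194989162487,0.7675
74,female,0.01991129531306815,0.765
75,female,0.021830043743310556,0.7625
76,female,0.02393369202465114,0.76
77,female,0.02624005799834371,0.7575
78,female,0.028768676518744436,0.755
79,female,0.031540964912973805,0.7525
80,female,0.034580404385069805,0.75
81,female,0.037912738901119784,0.7474999999999999
82,female,0.041566193239922646,0.745
83,female,0.045571712056064674,0.7424999999999999
84,female,0.04996322198026554,0.74
85,female,0.05477791897697822,0.7374999999999999
86,female,0.06005658339315212,0.735
87,female,0.06584392536661496,0.7324999999999999
88,female,0.07218896351967143,0.73
89,female,0.0791454401454432,0.7275
90,female,0.08677227640356666,0.725
91,female,0.0951340713807439,0.7224999999999999
92,female,0.10430164924317309,0.72
93,female,0.11435265911522707,0.7175
94,female,0.12537223276533432,0.715
95,female,0.1374537056696406,0.7124999999999999
96,female,0.1506994075608446,0.71
97,female,0.16522152915812968,0.7075
98,female,0.18114307241937347,0.705
99,female,0.19859889236423905,0.7025
100,female,0.21773683929236598,0.7
101,female,0.2387190110712144,0.6975
102,female,0.2617231261004007,0.695
103,female,0.2869440285815007,0.6925
104,female,0.31459533884291,0.69
105,female,0.3449112626979616,0.6875
106,female,0.37814857516152073,0.6849999999999999
107,female,0.4145887953270746,0.6825
108,female,0.45454057082546867,0.6799999999999999
109,female,0.49834229206157815,0.6775
110,female,0.546364958371438,0.6749999999999999
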