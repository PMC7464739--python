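age	annual_death_prob
60	0.011000
61	0.011996
62	0.013081
63	0.014265
64	0.015556
65	0.016964
66	0.018500
67	0.020174
68	0.022000
69	0.023991
70	0.026163
71	0.028530
72	0.031113
73	0.033929
74	0.036999
75	0.040348
76	0.044000
77	0.047982
78	0.052325
79	0.057061
80	0.062225
81	0.067857
82	0.073999
83	0.080696
84	0.088000
85	0.095965
86	0.104650
87	0.114122
88	0.124451
89	0.135715
90	0.147998
91	0.161393
92	0.176000
93	0.191929
94	0.209300
95	0.228244
96	0.248902
97	0.271429
98	0.295996
99	0.322785
100	0.352000
101	0.383859
102	0.418601
103	0.456488
104	0.497803
105	0.542858
106	0.591991
107	0.645571
108	0.704000
109	0.767717
110	0.837202
111	0.912975
112	0.995606
113	0.999000
114	0.999000
115	0.999000
116	0.999000
117	0.999000
118	0.999000
119	0.999000
120	0.999000
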