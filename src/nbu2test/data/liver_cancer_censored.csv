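# Ages (days) of 51 liver cancer patients: 39 observed events, 12 right-censored.
time,event
10,1
14,1
14,1
14,1
14,1
14,1
15,1
17,1
18,1
20,1
20,1
20,1
20,1
20,1
23,1
23,1
24,1
26,1
30,1
30,1
31,1
40,1
49,1
51,1
52,1
60,1
61,1
67,1
71,1
74,1
75,1
87,1
96,1
105,1
107,1
107,1
107,1
116,1
150,1
30,0
30,0
30,0
30,0
30,0
60,0
150,0
150,0
150,0
150,0
150,0
185,0
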