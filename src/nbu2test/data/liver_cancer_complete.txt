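# Survival times (days) of 39 liver cancer patients (complete data).
10
14
14
14
14
14
15
17
18
20
20
20
20
20
23
23
24
26
30
30
31
40
49
51
52
60
61
67
71
74
75
87
96
105
107
107
107
116
150
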