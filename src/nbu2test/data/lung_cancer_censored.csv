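# Survival (weeks) of 61 unresectable lung cancer patients on cyclophosphamide:
# 33 observed events, 28 right-censored (therapy terminated).
time,event
0.43,1
2.86,1
3.14,1
3.14,1
3.43,1
3.43,1
3.71,1
3.86,1
6.14,1
6.86,1
9.00,1
9.43,1
10.71,1
10.86,1
11.14,1
13.00,1
14.43,1
15.71,1
18.43,1
18.57,1
20.71,1
29.14,1
29.71,1
40.57,1
48.57,1
49.43,1
53.86,1
61.86,1
66.57,1
68.71,1
68.96,1
72.86,1
72.86,1
0.14,0
0.14,0
0.29,0
0.43,0
0.57,0
0.57,0
1.86,0
3.00,0
3.00,0
3.29,0
3.29,0
6.00,0
6.00,0
6.14,0
8.71,0
10.57,0
11.86,0
15.57,0
16.57,0
17.29,0
18.71,0
21.29,0
23.86,0
26.00,0
27.57,0
32.14,0
33.14,0
47.29,0
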