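n	q95	q98	q99
5	0.882897	1.17189	1.38849
10	0.525925	0.667885	0.752876
15	0.388132	0.486231	0.556578
20	0.323144	0.413406	0.467084
25	0.28863	0.350084	0.39139
30	0.258019	0.320188	0.365255
35	0.235234	0.293309	0.331031
40	0.215066	0.265283	0.295422
45	0.206855	0.25257	0.284129
50	0.191667	0.235837	0.270402
55	0.18134	0.226473	0.256603
60	0.172598	0.213932	0.244309
65	0.165691	0.204694	0.235163
70	0.158049	0.195075	0.213855
75	0.154806	0.188446	0.212941
80	0.151963	0.185998	0.212013
85	0.143606	0.178592	0.201549
90	0.137717	0.173923	0.199664
95	0.137395	0.169832	0.194102
100	0.134282	0.162602	0.184573
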