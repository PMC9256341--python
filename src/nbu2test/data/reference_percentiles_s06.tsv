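n	q95	q98	q99
5	0.396275	0.502898	0.562419
10	0.221699	0.274836	0.299154
15	0.166089	0.206706	0.234874
20	0.145573	0.178422	0.196138
25	0.122991	0.150936	0.169784
30	0.10865	0.138144	0.166397
35	0.105987	0.127848	0.14191
40	0.0950951	0.129734	0.141408
45	0.0873638	0.115054	0.125216
50	0.0871117	0.108423	0.121646
55	0.0790283	0.10263	0.118798
60	0.073819	0.093089	0.0996918
65	0.0700623	0.082458	0.101185
70	0.0725355	0.0930558	0.100772
75	0.0691197	0.083419	0.0928818
80	0.065666	0.0828855	0.0962278
85	0.0645971	0.075949	0.0900691
90	0.0645374	0.076169	0.0858537
95	0.0621102	0.077558	0.0897414
100	0.0613547	0.0794837	0.0925321
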