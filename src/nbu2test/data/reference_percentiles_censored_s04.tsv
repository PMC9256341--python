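n	q95	q98	q99
2	0.535606	0.583176	0.61155
4	0.0985967	0.106324	0.109739
6	0.0382919	0.0418751	0.0429949
8	0.0220675	0.0235447	0.0241831
10	0.0138634	0.0147497	0.0150687
12	0.00944369	0.00992625	0.010188
14	0.00667813	0.0071701	0.00738161
16	0.00489464	0.00550842	0.00565949
18	0.00372462	0.00419779	0.00434607
20	0.00266338	0.00307783	0.00332981
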