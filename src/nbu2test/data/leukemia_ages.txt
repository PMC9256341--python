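# Ages (years) of 40 leukemia patients; transcribed exactly as published,
# including the duplicated 4.381 and the out-of-order final entry.
0.315
0.496
0.616
1.145
1.208
1.263
1.414
2.025
2.036
2.162
2.211
2.370
2.532
2.693
2.805
2.910
2.912
3.192
3.263
3.348
3.348
3.427
3.499
3.534
3.767
3.751
3.858
3.986
4.049
4.244
4.323
4.381
4.392
4.397
4.647
4.753
4.929
4.973
5.074
4.381
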