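n	q95	q98	q99
2	0.007199	0.0296232	0.0501468
4	0.00717465	0.00973058	0.0118462
6	0.00292626	0.00471896	0.00502581
8	0.00186656	0.0023683	0.00269643
10	0.0012502	0.00168057	0.00182981
12	0.00073221	0.00102515	0.00114684
14	0.00035340	0.00072136	0.00083496
16	0.00018206	0.00041354	0.00061089
18	0.00003021	0.00026197	0.00041052
20	0.0000427	0.00015384	0.00029494
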