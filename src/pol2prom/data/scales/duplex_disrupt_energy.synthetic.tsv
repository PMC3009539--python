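# name: duplex_disrupt_energy
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	1.5681
AC	-0.7524
AG	-0.1694
AT	0.915
CA	2.1779
CC	-0.8901
CG	1.1728
CT	0.3402
GA	1.0301
GC	-2.3724
GG	0.1004
GT	-0.325
TA	-0.1226
TC	0.4269
TG	0.0565
TT	1.7985
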