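# name: helical_roll
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	0.772
AC	0.6156
AG	1.6547
AT	-0.8996
CA	-1.9083
CC	-0.054
CG	0.0649
CT	1.1441
GA	-0.1126
GC	-1.2814
GG	-1.4663
GT	2.2376
TA	-0.0761
TC	-0.4157
TG	-0.7308
TT	-1.2765
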