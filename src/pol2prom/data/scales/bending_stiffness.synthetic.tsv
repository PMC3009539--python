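# name: bending_stiffness
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	0.2499
AC	1.2822
AG	0.9853
AT	0.8771
CA	0.55
CC	2.7785
CG	0.8945
CT	0.0194
GA	-0.8464
GC	1.5284
GG	-0.6166
GT	1.3378
TA	-1.7004
TC	0.767
TG	-1.3684
TT	0.457
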