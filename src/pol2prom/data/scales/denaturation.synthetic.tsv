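# name: denaturation
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	-0.4797
AC	1.167
AG	-1.0706
AT	-2.0548
CA	1.218
CC	0.1523
CG	-0.1071
CT	-0.0044
GA	-0.4331
GC	-1.796
GG	-0.9569
GT	-0.5202
TA	0.909
TC	-1.1625
TG	0.4269
TT	0.2298
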