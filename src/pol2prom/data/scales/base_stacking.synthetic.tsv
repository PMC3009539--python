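# name: base_stacking
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	-0.6911
AC	1.0433
AG	1.4503
AT	-0.291
CA	2.2767
CC	-1.7541
CG	-0.8745
CT	-0.1942
GA	-0.3585
GC	-1.0512
GG	-0.8444
GT	2.4851
TA	0.0241
TC	0.5198
TG	0.4194
TT	-0.4475
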