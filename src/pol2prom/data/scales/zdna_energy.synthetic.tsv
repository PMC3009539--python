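# name: zdna_energy
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	0.4712
AC	0.9126
AG	-1.1354
AT	-1.6579
CA	-0.3954
CC	-1.6503
CG	-1.4334
CT	0.0604
GA	1.389
GC	-0.142
GG	0.4766
GT	-0.0753
TA	-0.5942
TC	-1.7638
TG	0.4568
TT	-0.6264
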