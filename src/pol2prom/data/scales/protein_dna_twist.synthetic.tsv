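# name: protein_dna_twist
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	-0.1933
AC	0.7603
AG	1.1684
AT	-1.4095
CA	-0.5786
CC	0.1595
CG	0.5017
CT	1.3805
GA	0.1365
GC	-1.1989
GG	-1.1006
GT	-1.2595
TA	1.8949
TC	-0.9459
TG	0.8118
TT	1.387
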