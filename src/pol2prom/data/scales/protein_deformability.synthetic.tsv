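# name: protein_deformability
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	0.3569
AC	0.186
AG	-0.5731
AT	-0.1474
CA	-1.9626
CC	0.01
CG	0.8599
CT	0.6047
GA	-0.6917
GC	1.1587
GG	1.7138
GT	-0.7834
TA	1.342
TC	0.4004
TG	1.3414
TT	-0.3096
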