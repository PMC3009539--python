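# name: helical_twist
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	0.9663
AC	0.2805
AG	0.4502
AT	-0.1452
CA	2.409
CC	1.0683
CG	-0.9509
CT	-0.2909
GA	0.7723
GC	-0.5942
GG	1.0171
GT	-1.1087
TA	0.2994
TC	-0.5866
TG	-1.6792
TT	-0.0533
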