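# name: bdna_twist
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	-0.1248
AC	-2.4168
AG	0.8068
AT	-0.1972
CA	-0.3283
CC	-0.1894
CG	-1.6674
CT	-0.0158
GA	-0.5183
GC	1.8546
GG	-1.4624
GT	1.0696
TA	1.3521
TC	-0.5098
TG	-0.9928
TT	-1.205
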