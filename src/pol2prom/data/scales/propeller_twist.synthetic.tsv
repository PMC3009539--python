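# name: propeller_twist
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	0.8245
AC	-0.0341
AG	-0.294
AT	1.5775
CA	0.2584
CC	-0.013
CG	0.2397
CT	-0.3005
GA	-0.6941
GC	0.9409
GG	2.0109
GT	-0.2973
TA	0.6915
TC	-1.4886
TG	-0.3748
TT	-0.0385
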