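# name: helical_tilt
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	-1.7426
AC	-0.2833
AG	0.8109
AT	0.1201
CA	0.1591
CC	0.2753
CG	-1.7872
CT	0.2788
GA	0.0209
GC	-0.3941
GG	-0.7802
GT	0.4796
TA	-1.8688
TC	-1.2874
TG	0.7441
TT	-0.9223
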