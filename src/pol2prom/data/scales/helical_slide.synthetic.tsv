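# name: helical_slide
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	-0.2761
AC	-0.242
AG	-1.2533
AT	-2.7832
CA	1.1622
CC	-0.5691
CG	0.637
CT	0.8539
GA	-1.1014
GC	-1.0443
GG	0.8845
GT	1.2418
TA	0.3834
TC	0.0276
TG	-1.4889
TT	0.4781
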