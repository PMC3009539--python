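# name: a_philicity
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	-0.7142
AC	1.3918
AG	0.552
AT	0.4214
CA	0.6336
CC	-0.9525
CG	1.1982
CT	-0.349
GA	-0.2135
GC	0.7988
GG	0.1876
GT	0.6552
TA	-0.6748
TC	-0.5899
TG	0.7884
TT	-0.3832
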