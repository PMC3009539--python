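# name: helical_rise
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	1.3032
AC	-0.1425
AG	0.4972
AT	-1.8867
CA	-0.5863
CC	0.2971
CG	-1.7762
CT	3.0228
GA	-0.1704
GC	-0.1536
GG	-0.1858
GT	-0.9736
TA	-0.1358
TC	-0.7613
TG	0.377
TT	1.4247
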