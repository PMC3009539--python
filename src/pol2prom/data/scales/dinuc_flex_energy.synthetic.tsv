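# name: dinuc_flex_energy
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	-1.8199
AC	0.4688
AG	0.4516
AT	0.2399
CA	1.0328
CC	1.7658
CG	-0.0033
CT	-0.5092
GA	1.4475
GC	0.672
GG	-1.4094
GT	0.5292
TA	-1.7088
TC	0.1457
TG	-0.7564
TT	-0.2982
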