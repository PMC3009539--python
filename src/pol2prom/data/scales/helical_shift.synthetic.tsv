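# name: helical_shift
# k: 2
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AA	0.5864
AC	0.9212
AG	-1.0912
AT	0.61
CA	0.4104
CC	-0.8578
CG	-0.1838
CT	-0.8713
GA	0.0154
GC	0.2819
GG	0.5686
GT	-1.4132
TA	0.2147
TC	0.2594
TG	0.3172
TT	-1.5719
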