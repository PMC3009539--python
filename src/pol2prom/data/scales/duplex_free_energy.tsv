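# name: duplex_free_energy
# k: 2
# citation: SantaLucia (1998) unified nearest-neighbor dG37
# synthetic: false
AA	-1
AC	-1.44
AG	-1.28
AT	-0.88
CA	-1.45
CC	-1.84
CG	-2.17
CT	-1.28
GA	-1.3
GC	-2.24
GG	-1.84
GT	-1.44
TA	-0.58
TC	-1.3
TG	-1.45
TT	-1
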