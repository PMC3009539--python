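# name: eiip
# k: 1
# citation: Nair & Sreenadhan (2006) electron-ion interaction pseudopotential
# synthetic: false
A	0.126
C	0.134
G	0.0806
T	0.1335
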