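# name: nucleosome_preference
# k: 3
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AAA	-0.0412
AAC	1.4465
AAG	-0.6304
AAT	-0.8713
ACA	-0.578
ACC	-0.5134
ACG	0.9332
ACT	0.589
AGA	-1.1978
AGC	0.4615
AGG	-0.7269
AGT	0.7771
ATA	-1.0093
ATC	0.4015
ATG	0.0347
ATT	1.2192
CAA	2.6321
CAC	-1.0251
CAG	-0.0585
CAT	0.6256
CCA	-0.0567
CCC	0.2042
CCG	0.4717
CCT	-0.9332
CGA	-1.665
CGC	0.1001
CGG	0.7596
CGT	-0.3642
CTA	-0.2286
CTC	0.1977
CTG	-0.4691
CTT	0.5375
GAA	-1.0651
GAC	0.089
GAG	1.5114
GAT	-0.2072
GCA	1.4776
GCC	1.8993
GCG	-0.5992
GCT	-0.4721
GGA	0.3395
GGC	0.9876
GGG	-0.5191
GGT	-0.7209
GTA	-1.1541
GTC	0.1356
GTG	-1.134
GTT	1.8061
TAA	-0.7628
TAC	0.5555
TAG	0.0471
TAT	0.1942
TCA	-0.4316
TCC	-1.2411
TCG	-0.598
TCT	-1.2315
TGA	-0.4008
TGC	0.9687
TGG	-1.1525
TGT	1.0643
TTA	-1.4401
TTC	0.7736
TTG	-1.3412
TTT	-0.2813
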