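# name: trinuc_bendability
# k: 3
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AAA	0.2096
AAC	1.5776
AAG	-0.1908
AAT	1.2322
ACA	-2.9485
ACC	0.7842
ACG	0.1042
ACT	-1.5261
AGA	0.6652
AGC	0.5265
AGG	1.0886
AGT	-1.909
ATA	-1.2511
ATC	0.14
ATG	0.3404
ATT	1.2456
CAA	-0.5912
CAC	0.2922
CAG	0.3755
CAT	0.0228
CCA	-1.4514
CCC	1.5067
CCG	-2.0489
CCT	-2.3669
CGA	-0.3194
CGC	1.6688
CGG	0.0327
CGT	-0.1625
CTA	1.6835
CTC	1.002
CTG	0.4108
CTT	-0.5385
GAA	0.2886
GAC	1.2243
GAG	0.6268
GAT	0.2193
GCA	-0.0859
GCC	1.6705
GCG	-0.6123
GCT	0.2014
GGA	0.9009
GGC	0.7738
GGG	0.9658
GGT	1.2628
GTA	-0.9103
GTC	-0.8105
GTG	0.1112
GTT	1.9343
TAA	-0.3435
TAC	1.1593
TAG	0.8731
TAT	1.6087
TCA	-1.192
TCC	-0.6661
TCG	0.188
TCT	-0.9891
TGA	-0.1955
TGC	-0.1099
TGG	-0.265
TGT	-0.924
TTA	-0.0212
TTC	-1.5335
TTG	1.614
TTT	0.9033
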