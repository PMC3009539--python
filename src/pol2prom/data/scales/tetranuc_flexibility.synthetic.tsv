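# name: tetranuc_flexibility
# k: 4
# citation: synthetic stand-in
# synthetic: true
# note: deterministic synthetic stand-in values, not the published table
AAAA	1.1165
AAAC	0.512
AAAG	-0.4636
AAAT	-2.0625
AACA	0.7623
AACC	-0.1572
AACG	3.3699
AACT	-0.0701
AAGA	0.9211
AAGC	0.3592
AAGG	-0.1799
AAGT	-1.2031
AATA	-0.1331
AATC	-0.5811
AATG	-0.4598
AATT	-1.616
ACAA	-0.7173
ACAC	0.5235
ACAG	0.1943
ACAT	0.9886
ACCA	-2.2192
ACCC	0.8277
ACCG	-0.7581
ACCT	1.3953
ACGA	-0.214
ACGC	-0.7965
ACGG	0.8007
ACGT	2.0508
ACTA	1.2729
ACTC	1.0449
ACTG	0.2928
ACTT	0.9408
AGAA	-0.4622
AGAC	0.6412
AGAG	-0.9977
AGAT	0.2416
AGCA	-0.4956
AGCC	-2.4379
AGCG	-1.9712
AGCT	1.2578
AGGA	-0.0195
AGGC	1.1807
AGGG	0.6584
AGGT	-1.433
AGTA	0.8759
AGTC	-0.3307
AGTG	1.2948
AGTT	1.1255
ATAA	0.6692
ATAC	-0.8394
ATAG	-0.1059
ATAT	-0.9458
ATCA	-0.0722
ATCC	-1.6291
ATCG	-0.5428
ATCT	1.0289
ATGA	-0.0547
ATGC	-0.2665
ATGG	1.2694
ATGT	1.0677
ATTA	2.3213
ATTC	0.5576
ATTG	-0.4
ATTT	2.1357
CAAA	1.3185
CAAC	-0.5411
CAAG	0.9687
CAAT	1.2841
CACA	-0.4724
CACC	0.2123
CACG	-0.1359
CACT	0.4255
CAGA	-0.17
CAGC	0.2649
CAGG	0.0125
CAGT	-1.3643
CATA	-0.4854
CATC	-0.431
CATG	0.1964
CATT	-0.4217
CCAA	-0.4053
CCAC	1.7783
CCAG	0.297
CCAT	0.4793
CCCA	-0.4977
CCCC	1.2708
CCCG	0.6663
CCCT	-1.108
CCGA	1.1087
CCGC	-0.2327
CCGG	0.8903
CCGT	-0.8039
CCTA	-0.5513
CCTC	-0.2088
CCTG	0.5127
CCTT	0.1345
CGAA	0.1337
CGAC	0.626
CGAG	-0.3224
CGAT	-1.1948
CGCA	-0.736
CGCC	1.088
CGCG	1.1157
CGCT	-0.6224
CGGA	-1.2304
CGGC	-0.3155
CGGG	0.1675
CGGT	-0.9823
CGTA	0.2184
CGTC	-0.2668
CGTG	-0.1615
CGTT	1.5046
CTAA	-0.7084
CTAC	-1.0035
CTAG	0.7222
CTAT	2.4961
CTCA	0.8438
CTCC	-0.1354
CTCG	-0.1165
CTCT	0.2752
CTGA	0.3998
CTGC	-0.4793
CTGG	-0.6431
CTGT	0.5562
CTTA	-0.7488
CTTC	1.2853
CTTG	-0.4358
CTTT	-0.5262
GAAA	0.0901
GAAC	0.0485
GAAG	-0.424
GAAT	-1.2368
GACA	-1.9113
GACC	0.3937
GACG	0.3544
GACT	1.8322
GAGA	-1.711
GAGC	-0.411
GAGG	0.2399
GAGT	0.3665
GATA	-0.5395
GATC	0.4585
GATG	-0.7441
GATT	-0.2248
GCAA	-0.0601
GCAC	0.2437
GCAG	0.6847
GCAT	0.3492
GCCA	0.1655
GCCC	1.89
GCCG	-1.1905
GCCT	1.5505
GCGA	1.1648
GCGC	2.2679
GCGG	0.2107
GCGT	-0.9522
GCTA	-0.4843
GCTC	-0.982
GCTG	-0.2285
GCTT	-0.0284
GGAA	1.2107
GGAC	-1.3232
GGAG	1.9632
GGAT	-1.0222
GGCA	-1.6187
GGCC	-0.796
GGCG	0.5736
GGCT	1.0728
GGGA	-0.9569
GGGC	-0.97
GGGG	0.777
GGGT	0.3284
GGTA	-1.1427
GGTC	-0.2935
GGTG	-0.6717
GGTT	0.2378
GTAA	-1.6032
GTAC	0.3404
GTAG	-1.191
GTAT	-0.5158
GTCA	-0.6113
GTCC	0.4728
GTCG	0.633
GTCT	-0.1512
GTGA	-1.0108
GTGC	-0.6395
GTGG	-1.1093
GTGT	-0.9819
GTTA	1.7514
GTTC	0.0617
GTTG	0.5927
GTTT	-1.8962
TAAA	1.0501
TAAC	-2.357
TAAG	0.5629
TAAT	-0.5177
TACA	-2.4218
TACC	0.7296
TACG	-0.5628
TACT	0.3619
TAGA	1.0547
TAGC	-0.2295
TAGG	-0.028
TAGT	-0.5031
TATA	1.0804
TATC	-2.0028
TATG	-0.3477
TATT	0.8539
TCAA	0.3465
TCAC	-0.215
TCAG	-0.2968
TCAT	0.5653
TCCA	-0.3771
TCCC	0.7921
TCCG	-0.1135
TCCT	-0.0206
TCGA	-0.6116
TCGC	-0.8246
TCGG	-1.217
TCGT	0.2165
TCTA	-1.0172
TCTC	-0.1403
TCTG	1.95
TCTT	0.4841
TGAA	-1.3524
TGAC	1.9137
TGAG	-0.4349
TGAT	-2.8564
TGCA	-0.1087
TGCC	-1.5449
TGCG	-0.6896
TGCT	-1.5137
TGGA	1.828
TGGC	0.0991
TGGG	-0.3446
TGGT	-0.5216
TGTA	0.9004
TGTC	-0.8403
TGTG	-0.564
TGTT	0.9972
TTAA	-0.2333
TTAC	0.433
TTAG	-0.3963
TTAT	-0.2481
TTCA	0.7234
TTCC	-0.3916
TTCG	-1.2664
TTCT	1.1058
TTGA	0.2849
TTGC	1.1798
TTGG	1.7195
TTGT	-2.0808
TTTA	1.2645
TTTC	0.7852
TTTG	0.3002
TTTT	-1.0027
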