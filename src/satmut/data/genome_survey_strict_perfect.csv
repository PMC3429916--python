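unit_length,motif,n_loci
2,AC,21
2,AG,265
2,AT,97
2,CG,0
3,AAC,32
3,AAG,3
3,AAT,57
3,ACC,2
3,ACG,2
3,ACT,3
3,AGC,3
3,AGG,3
3,ATC,28
3,CCG,0
4,AAAC,0
4,AAAG,1
4,AAAT,4
4,AACC,0
4,AACG,0
4,AACT,2
4,AAGC,0
4,AAGG,0
4,AAGT,0
4,AATC,8
4,AATG,29
4,AATT,3
4,ACAG,0
4,ACAT,1
4,ACCC,0
4,ACCG,0
4,ACCT,0
4,ACGC,0
4,ACGG,0
4,ACGT,0
4,ACTC,1
4,ACTG,0
4,AGAT,2
4,AGCG,0
4,AGCT,0
4,AGGC,0
4,AGGG,1
4,ATCC,0
4,ATCG,0
4,ATGC,0
4,CAGC,1
4,CCCG,0
4,CCGG,0
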