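marker_id,chromosome,unit,repeat_count,percent_match,magnitudes
M21,II,GGGCAC,11,51,
M01,I,CT,55,55,
M15,II,TC,57,55,
M41,V,TCT,26,59,
M07,I,TTG,18,64,
M43,V,TTAA,15,69,
M29,III,TTAA,10,72,
M16,II,TGA,15,73,
M35,IV,CTCC,20,73,
M42,V,AATT,9,75,
M13,I,CTTAAC,6,78,
M08,I,TAAT,3,81,
M47,X,GT,7,84,
M06,I,AAC,16,85,
M34,IV,AT,17,85,+1(1)
M26,III,TTA,29,85,
M04,I,CAA,11,87,
M22,II,GAATAA,5,88,
M45,V,GAGAG,3,91,
M11,I,TTCTT,3,92,
M33,IV,AG,17,93,
M14,I,GAATAA,4,95,
M28,III,TGG,3,100,
M18,II,TCT,3,100,
M17,II,GTT,3,100,-1(1)
M19,II,TCGA,3,100,
M38,IV,AAGCCT,6,100,
M03,I,TC,7,100,
M05,I,AGT,8,100,
M02,I,GA,13,100,
M25,III,AG,14,100,
M46,X,AG,15,100,
M84,III,CTCTTC,17,100,+1(1)
M74,V,CAA,33,100,-1(1);+1(1)
M77,X,ACAT,35,100,+1(1)
M78,I/V,ACAT,36,100,+1(2);-9(1)
M79,I,TTAG,40,100,+1(4)
M82,X,TGAAT,43,100,-3(1);-1(1);+1(2);+2(1);+3(1)
M88,?,TC,59,100,-1(2);-2(1)
M80,?,CAGC,64,100,+1(2)
M83,?,TTCAA,64,100,+1(7)
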