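locus	start	end
MT-DLOOP	16024	16569
MT-DLOOP	1	576
MT-RNR1	648	1601
MT-RNR2	1671	3229
MT-ND1	3307	4262
MT-ND2	4470	5511
MT-CO1	5904	7445
MT-CO2	7586	8269
MT-ATP8	8366	8572
MT-ATP6	8527	9207
MT-CO3	9207	9990
MT-ND3	10059	10404
MT-ND4L	10470	10766
MT-ND4	10760	12137
MT-ND5	12337	14148
MT-ND6	14149	14673
MT-CYB	14747	15887
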