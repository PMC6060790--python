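chrom	start	end	symbol
1	51435638	51440309	CDKN2C
1	204485511	204527248	MDM4
2	16080683	16087129	MYCN
2	121554866	121750229	GLI2
4	1795039	1810599	FGFR3
4	55095264	55164414	PDGFRA
5	1253282	1295184	TERT
6	135502453	135540311	MYB
7	55086714	55324313	EGFR
7	92234235	92465908	CDK6
7	116312444	116438440	MET
7	128828713	128853386	SMO
7	140419127	140624564	BRAF
8	38268656	38326352	FGFR1
8	67474409	67525484	MYBL1
8	128748315	128753680	MYC
9	21967751	22009312	CDKN2A/B
9	98205264	98279247	PTCH1
10	89623195	89728532	PTEN
10	104263744	104403056	SUFU
11	69455873	69469242	CCND1
12	4382902	4414522	CCND2
12	58141510	58146916	CDK4
12	69201956	69239214	MDM2
13	48877883	49056026	RB1
17	7571720	7590868	TP53
17	29421945	29709134	NF1
17	58677544	58743585	PPM1D
22	24129150	24176703	SMARCB1
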