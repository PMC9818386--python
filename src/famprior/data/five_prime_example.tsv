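family	gene	variant_key	cadd	cons_score	promoter	cpg	segway	chmm	histone	n_tfs
Family_1	SP5	2_171571426_G_A	16.65	2	yes	yes	GS	TssA,TssAFlnk,Tx,TxFlnk,TxWk	H3K27Ac,H3K4Me1,H3K4Me3	13
Family_1	FNDC3B	3_171757553_C_A	15.8	2	yes	yes	TSS	TssA,TssAFlnk	H3K27Ac,H3K4Me3	40
Family_1	CAMK2D	4_114682943_TCCTCCTCCGGCG_T	19.58	3	unknown	no	TF2	ReprPC,RepPCWk,Quies	H3K27Ac,H3K4Me3	2
Family_1	FOXJ2	12_8185317_GGAGCC_G	21.9	2	yes	yes	TSS	TssA,TssAFlnk,TssBiv,EnhBiv	H3K27Ac,H3K4Me3	29
Family_1	SPTB	14_65346721_C_A	20.5	2	unknown	yes	TSS	ReprPC,RepPCWk,Quies		NA
Family_2	NRBF2	10_64893005_T_C	17.12	2	yes	yes	TSS	ReprPC,RepPCWk,Quies	H3K4Me3	1
Family_4	HMGXB4	22_35653479_C_A	20.3	2	yes	yes	TSS	TssA,TssAFlnk	H3K27Ac,H3K4Me3	15
Family_6	ERBB4	2_213404066_C_T	17.09	2	unknown	no	D	TssA,TssAFlnk		7
Family_6	AGFG1	2_228337132_G_A	16.16	2	yes	yes	GS	TssA,TssAFlnk	H3K27Ac,H3K4Me3	8
Family_6	ING2	4_184425877_C_A	15.71	3	yes	yes	TSS	TssA,TssAFlnk	H3K4Me3	12
Family_6	PIK3R1	5_67511017_G_C	16.81	1	unknown	yes	TSS	Enh,ReprPC,RepPCWk,Quies	H3K27Ac,H3K4Me3	3
Family_6	MDFIC	7_114562322_C_G	21.1	2	yes	yes	TF0	TssBiv,Biv,EnhBiv,TssA,TssAFlnk	H3K27Ac,H3K4Me3	7
Family_6	TBC1D4	13_76056522_G_A	18.11	2	yes	yes	GS	TssA,TssAFlnk,ReprPC,RepPCWk,Quies	H3K27Ac,H3K4Me3	1
Family_7	ERBB3	12_56473408_C_T	18.89	3	yes	yes	GS	TssA,TssAFlnk	H3K27Ac,H3K4Me1,H3K4Me3	69
Family_7	PSMC6	14_53173885_C_G	18.51	3	yes	yes	TSS	TssA,TssAFlnk	H3K27Ac,H3K4Me3	13
Family_9	CAMK1	3_9811535_G_A	21.1	2	yes	yes	TSS	TssA,TssAFlnk,TssBiv,EnhBiv	H3K4Me3	18
Family_9	PLEKHG1	6_150921086_G_A	15.37	3	yes	yes	TF0	TssA,TssAFlnk,TssBiv,EnhBiv	H3K4Me3	11
Family_10	PTK2	8_142012766_C_T	15.65	1	unknown	no	GS	TssA,TssAFlnk	H3K27Ac,H3K4Me1	39
Family_11	DLG1	3_197024641_C_T	20.2	2	yes	yes	TSS	Enh	H3K27Ac,H3K4Me3	1
Family_11	APBB1IP	10_26727608_C_G	15.3	2	unknown	yes	TF0	ReprPC,RepPCWk,Quies	H3K27Ac,H3K4Me3	NA
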