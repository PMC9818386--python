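family	gene	variant_key	cadd	cons_score	mirna_binding	context_hi	mirsvr	segway	chmm
Family_1	LONRF1	8_12580093_G_C	19.75	3	yes	yes	-1.26	GE0	Tx,TxWk
Family_2	SLC35A1	6_88222026_A_G	16.88	2	yes	yes	-1.23	GE0	Tx,TxWk
Family_6	MARCHF8	10_45952965_T_C	16.16	3	yes	no	-0.78	GE0	Tx,TxWk
Family_10	B4GALT5	20_48250790_A_G	16.44	3	yes	no	-0.41	GE1	Tx,TxWk
Family_12	FAM76B	11_95504039_CA_C	15.82	3	yes	yes	-0.26	GE0	Tx,TxWk
Family_13	SGSM2	17_2284327_C_T	21.5	2	yes	yes	-1.22	GE1	Tx,TxWk
Family_2	FGFR1	8_38270114_C_T	17.46	1	yes	no	-0.11	R5	Tx,TxWk,ReprPC,PCWk,Quies
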