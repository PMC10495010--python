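name	uniprot	family	motif	pdb	interactions
GrxC1	Q8L8T2	Grx	CGYC		30
GrxC2	Q9FNE2	Grx	CPFC
GrxC3	Q9FVX1	Grx	CPFC		1
GrxC4	Q8LFQ6	Grx	CPFC		1
GrxC5	Q8GWS0	Grx	CSYC	3rhb,3rhc	2
GrxC6	Q8L9S3	Grx	CCMC		1
GrxC7	Q96305	Grx	CCMC
GrxC8	Q8LF89	Grx	CCMC		8
GrxC9	Q9SGP6	Grx	CCMC		9
GrxC10	Q29PZ1	Grx	CCMC		1
GrxC11	Q9LYC6	Grx	CCMC		1
GrxC12	O82254	Grx	CCMC		1
GrxC13	O82255	Grx	CCLC		1
GrxC14	Q9LYC5	Grx	CCLC		1
GrxS1	Q9SA68	Grx	CCMS		1
GrxS2	Q8L8Z8	Grx	CCMS		1
GrxS3	O23421	Grx	CCMS		10
GrxS4	O23419	Grx	CCMS
GrxS5	O23420	Grx	CCMS		1
GrxS6	Q9LYC8	Grx	CCMS		2
GrxS7	Q6NLU2	Grx	CCMS
GrxS8	O23417	Grx	CCMS
GrxS9	O04341	Grx	CCMS		5
GrxS10	Q9LIF1	Grx	CCMS		1
GrxS11	Q9M9Y9	Grx	CCLS		1
GrxS12	Q8LBS4	Grx	CSYS		5
GrxS13	Q84TF4	Grx	CCLG		2
GrxS14	Q84Y95	Grx	CGFS	3ipz,2mma	4
GrxS15	Q8LBK6	Grx	CGFS		16
GrxS16	Q8H7F6	Grx	CGFS	2lwf	7
GrxS17	Q9ZPH2	Grx	3·CGFS		28
Trxf1	Q9XFH8	Trx	CGPC
Trxf2	Q9XFH9	Trx	CGPC	7c2b
Trxh1	P29448	Trx	CGPC	1xfl	47
Trxh2	Q38879	Trx	CGPC
Trxh3	Q42403	Trx	CPPC		73
Trxh4	Q39239	Trx	CPPC		1
Trxh5	Q39241	Trx	CPPC		80
Trxh7	Q9XIF4	Trx	CGPC		97
Trxh8	Q9CAS1	Trx	CGPC		6
Trxh9	Q9C9Y6	Trx	CGPC		5
Trxh10	Q9LXZ8	Trx	CVPC
Trxm1	O48737	Trx	CGPC	7c65	2
Trxm2	Q9SEU8	Trx	CGPC	7c3f	4
Trxm3	Q9SEU7	Trx	CGPC
Trxm4	Q9SEU6	Trx	CGPC		6
Trxo1	O64764	Trx	CGPC	6g61
Trxo2	Q93VQ9	Trx	CGPC
Trxx	Q8LD49	Trx	CGPC		2
Trxy1	Q6NPF9	Trx	CGPC	7bzk	14
Trxy2	Q8L7S9	Trx	CGPC		72
CITRX / Trxz	Q9M7X9	Trx	CGPC		2
Nrx1	O80763	Trx	2·CGPC		1
Nrx3	Q8VZQ0	Trx	CRPC
F4HPP4	F4HPP4	Trx	CGPC
TR164 / HCF164	O23166	Trx	CEVC		1
Trl11 / Lilium1	O64654	Trx	CGGC
Trl22 / Lilium2	Q8LCT3	Trx	CASC
Trl12 / Lilium3	Q9XFI1	Trx	CGGC
Trl13 / Lilium4	O22779	Trx	CGGC		1
Trl21 / Lilium5	Q8LEK4	Trx	CGSC	6lyx,6lyw
Trl4 / Lilium6	Q9C5C5	Trx	CGSC
Trl33	Q8LCH9	Trx	CGVC
CXXS1	Q8LDI5	Trx	CIPS
CXXS2	Q8GXV2	Trx	CLPS
Trl31 / WCRK1	Q9FG36	Trx	CRKC
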