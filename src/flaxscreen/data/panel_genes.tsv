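gene_id	family
4CL1	lignin
4CL2	lignin
4CL3	lignin
4CL4	lignin
4CL5	lignin
4CL6	lignin
4CL7	lignin
4CL8	lignin
4CL9	lignin
C3'H1	lignin
C3'H2	lignin
C3'H3	lignin
C4H1	lignin
C4H2	lignin
C4H3	lignin
C4H4	lignin
C4H5	lignin
CAD1A	lignin
CAD1B	lignin
CAD2A	lignin
CAD2B	lignin
CAD3A	lignin
CAD3B	lignin
CAD4A	lignin
CAD4B	lignin
CAD5A	lignin
CAD5B	lignin
CAD6	lignin
CAD7	lignin
CAD8	lignin
CCoAOMT1	lignin
CCoAOMT2	lignin
CCoAOMT3	lignin
CCoAOMT4	lignin
CCoAOMT5	lignin
CCR1	lignin
CCR10	lignin
CCR11	lignin
CCR12	lignin
CCR2	lignin
CCR3	lignin
CCR4	lignin
CCR5	lignin
CCR6	lignin
CCR7	lignin
CCR8	lignin
CCR9	lignin
COMT1	lignin
COMT2	lignin
COMT3	lignin
F5H1	lignin
F5H2	lignin
F5H3	lignin
F5H4	lignin
F5H5	lignin
F5H6	lignin
F5H7	lignin
F5H8	lignin
HCT1	lignin
HCT2	lignin
HCT3	lignin
HCT4	lignin
HCT5	lignin
PAL1	lignin
PAL2	lignin
PAL3	lignin
CTL1	CTL
CTL10	CTL
CTL11	CTL
CTL12	CTL
CTL13	CTL
CTL14	CTL
CTL16	CTL
CTL17	CTL
CTL18	CTL
CTL19	CTL
CTL2	CTL
CTL20	CTL
CTL21	CTL
CTL22	CTL
CTL23	CTL
CTL24	CTL
CTL25	CTL
CTL26	CTL
CTL27	CTL
CTL28	CTL
CTL29	CTL
CTL3	CTL
CTL30	CTL
CTL31	CTL
CTL32	CTL
CTL33	CTL
CTL35	CTL
CTL36	CTL
CTL37	CTL
CTL4	CTL
CTL5	CTL
CTL6	CTL
CTL7	CTL
CTL8	CTL
CTL9	CTL
BGAL1	BGAL
BGAL10	BGAL
BGAL11	BGAL
BGAL12	BGAL
BGAL13	BGAL
BGAL14	BGAL
BGAL16	BGAL
BGAL18	BGAL
BGAL19	BGAL
BGAL2	BGAL
BGAL20	BGAL
BGAL21	BGAL
BGAL22	BGAL
BGAL23	BGAL
BGAL24	BGAL
BGAL25	BGAL
BGAL26	BGAL
BGAL27	BGAL
BGAL28	BGAL
BGAL29	BGAL
BGAL3	BGAL
BGAL30	BGAL
BGAL31	BGAL
BGAL32	BGAL
BGAL33	BGAL
BGAL34	BGAL
BGAL35	BGAL
BGAL36	BGAL
BGAL37	BGAL
BGAL38	BGAL
BGAL39	BGAL
BGAL4	BGAL
BGAL40	BGAL
BGAL41	BGAL
BGAL42	BGAL
BGAL43	BGAL
BGAL6	BGAL
BGAL7	BGAL
BGAL8	BGAL
BGAL9	BGAL
ABCA1	ABC_HMA
ABCA2	ABC_HMA
ABCA3	ABC_HMA
ABCA4	ABC_HMA
ABCA5	ABC_HMA
ABCA6	ABC_HMA
ABCA7	ABC_HMA
ABCA8	ABC_HMA
ABCB1	ABC_HMA
ABCB10	ABC_HMA
ABCB11	ABC_HMA
ABCB12	ABC_HMA
ABCB13	ABC_HMA
ABCB14	ABC_HMA
ABCB15	ABC_HMA
ABCB16	ABC_HMA
ABCB17	ABC_HMA
ABCB18	ABC_HMA
ABCB19	ABC_HMA
ABCB2	ABC_HMA
ABCB20	ABC_HMA
ABCB21	ABC_HMA
ABCB22	ABC_HMA
ABCB23	ABC_HMA
ABCB24	ABC_HMA
ABCB25	ABC_HMA
ABCB26	ABC_HMA
ABCB27	ABC_HMA
ABCB28	ABC_HMA
ABCB29	ABC_HMA
ABCB3	ABC_HMA
ABCB30	ABC_HMA
ABCB31	ABC_HMA
ABCB32	ABC_HMA
ABCB33	ABC_HMA
ABCB34	ABC_HMA
ABCB35	ABC_HMA
ABCB36	ABC_HMA
ABCB37	ABC_HMA
ABCB38	ABC_HMA
ABCB39	ABC_HMA
ABCB4	ABC_HMA
ABCB40	ABC_HMA
ABCB41	ABC_HMA
ABCB42	ABC_HMA
ABCB43	ABC_HMA
ABCB44	ABC_HMA
ABCB45	ABC_HMA
ABCB46	ABC_HMA
ABCB47	ABC_HMA
ABCB48	ABC_HMA
ABCB5	ABC_HMA
ABCB6	ABC_HMA
ABCB7	ABC_HMA
ABCB8	ABC_HMA
ABCB9	ABC_HMA
ABCC1	ABC_HMA
ABCC10	ABC_HMA
ABCC11	ABC_HMA
ABCC12	ABC_HMA
ABCC13	ABC_HMA
ABCC14	ABC_HMA
ABCC15	ABC_HMA
ABCC16	ABC_HMA
ABCC17	ABC_HMA
ABCC18	ABC_HMA
ABCC19	ABC_HMA
ABCC2	ABC_HMA
ABCC3	ABC_HMA
ABCC4	ABC_HMA
ABCC5	ABC_HMA
ABCC6	ABC_HMA
ABCC7	ABC_HMA
ABCC8	ABC_HMA
ABCC9	ABC_HMA
ABCD1	ABC_HMA
ABCD2	ABC_HMA
ABCD3	ABC_HMA
ABCD4	ABC_HMA
ABCD5	ABC_HMA
ABCE1	ABC_HMA
ABCE2	ABC_HMA
ABCF1	ABC_HMA
ABCF2	ABC_HMA
ABCF3	ABC_HMA
ABCF4	ABC_HMA
ABCF5	ABC_HMA
ABCF6	ABC_HMA
ABCF7	ABC_HMA
ABCF8	ABC_HMA
ABCF9	ABC_HMA
ABCG1	ABC_HMA
ABCG11	ABC_HMA
ABCG12	ABC_HMA
ABCG13	ABC_HMA
ABCG14	ABC_HMA
ABCG16	ABC_HMA
ABCG17	ABC_HMA
ABCG18	ABC_HMA
ABCG19	ABC_HMA
ABCG2	ABC_HMA
ABCG20	ABC_HMA
ABCG21	ABC_HMA
ABCG22	ABC_HMA
ABCG23	ABC_HMA
ABCG24	ABC_HMA
ABCG25	ABC_HMA
ABCG26	ABC_HMA
ABCG27	ABC_HMA
ABCG28	ABC_HMA
ABCG29	ABC_HMA
ABCG3	ABC_HMA
ABCG30	ABC_HMA
ABCG31	ABC_HMA
ABCG32	ABC_HMA
ABCG33	ABC_HMA
ABCG34	ABC_HMA
ABCG35	ABC_HMA
ABCG36	ABC_HMA
ABCG37	ABC_HMA
ABCG38	ABC_HMA
ABCG39	ABC_HMA
ABCG4	ABC_HMA
ABCG40	ABC_HMA
ABCG41	ABC_HMA
ABCG42	ABC_HMA
ABCG43	ABC_HMA
ABCG44	ABC_HMA
ABCG45	ABC_HMA
ABCG46	ABC_HMA
ABCG47	ABC_HMA
ABCG48	ABC_HMA
ABCG49	ABC_HMA
ABCG5	ABC_HMA
ABCG50	ABC_HMA
ABCG51	ABC_HMA
ABCG52	ABC_HMA
ABCG53	ABC_HMA
ABCG54	ABC_HMA
ABCG55	ABC_HMA
ABCG56	ABC_HMA
ABCG57	ABC_HMA
ABCG58	ABC_HMA
ABCG59	ABC_HMA
ABCG6	ABC_HMA
ABCG60	ABC_HMA
ABCG61	ABC_HMA
ABCG62	ABC_HMA
ABCG63	ABC_HMA
ABCG64	ABC_HMA
ABCG65	ABC_HMA
ABCG66	ABC_HMA
ABCG67	ABC_HMA
ABCG68	ABC_HMA
ABCG69	ABC_HMA
ABCG7	ABC_HMA
ABCG70	ABC_HMA
ABCG71	ABC_HMA
ABCG72	ABC_HMA
ABCG73	ABC_HMA
ABCG74	ABC_HMA
ABCG75	ABC_HMA
ABCG76	ABC_HMA
ABCG77	ABC_HMA
ABCG78	ABC_HMA
ABCG79	ABC_HMA
ABCG8	ABC_HMA
ABCG80	ABC_HMA
ABCG81	ABC_HMA
ABCG82	ABC_HMA
ABCG83	ABC_HMA
ABCG84	ABC_HMA
ABCG85	ABC_HMA
ABCG9	ABC_HMA
ABCH1	ABC_HMA
ABCH10	ABC_HMA
ABCH11	ABC_HMA
ABCH12	ABC_HMA
ABCH13	ABC_HMA
ABCH14	ABC_HMA
ABCH15	ABC_HMA
ABCH16	ABC_HMA
ABCH17	ABC_HMA
ABCH18	ABC_HMA
ABCH19	ABC_HMA
ABCH2	ABC_HMA
ABCH20	ABC_HMA
ABCH21	ABC_HMA
ABCH22	ABC_HMA
ABCH3	ABC_HMA
ABCH4	ABC_HMA
ABCH5	ABC_HMA
ABCH6	ABC_HMA
ABCH7	ABC_HMA
ABCH8	ABC_HMA
HMA1	ABC_HMA
HMA10	ABC_HMA
HMA11	ABC_HMA
HMA12	ABC_HMA
HMA2	ABC_HMA
HMA3	ABC_HMA
HMA4	ABC_HMA
HMA6	ABC_HMA
HMA7	ABC_HMA
HMA8	ABC_HMA
HMA9	ABC_HMA
DIR1	lignan
DIR2	lignan
DIR3	lignan
DIR4	lignan
DIR5	lignan
DIR6	lignan
PLR1	lignan
PLR2	lignan
UGT74S1	lignan
Alfa_TUB1	TUB
Alfa_TUB2	TUB
Alfa_TUB3	TUB
Alfa_TUB4	TUB
Alfa_TUB5	TUB
Alfa_TUB6	TUB
Beta_TUB1	TUB
Beta_TUB10	TUB
Beta_TUB11	TUB
Beta_TUB12	TUB
Beta_TUB13	TUB
Beta_TUB2	TUB
Beta_TUB3	TUB
Beta_TUB4	TUB
Beta_TUB5	TUB
Beta_TUB6	TUB
Beta_TUB7	TUB
Beta_TUB8	TUB
Beta_TUB9	TUB
Gamma_Tub1	TUB
Gamma_Tub2	TUB
CESA1-A	CESA
CESA1-B	CESA
CESA3-A	CESA
CESA3-B	CESA
CESA3-C	CESA
CESA4	CESA
CESA6-A	CESA
CESA6-B	CESA
CESA6-C	CESA
CESA6-D	CESA
CESA6-E	CESA
CESA6-F	CESA
CESA7-A	CESA
CESA7-B	CESA
CESA8-A	CESA
CESA8-B	CESA
RGL1_B	RGL
RGL2	RGL
RGL3_A	RGL
RGL3_B	RGL
RGL4_A	RGL
RGL4_B	RGL
RGL6_A	RGL
RGL6_B	RGL
RGL7_A	RGL
RGL7_B	RGL
FAD2A	FA
FAD2B	FA
FAD3A	FA
FAD3B	FA
SAD1	FA
SAD2	FA
Act1	ACT
Act10	ACT
Act11	ACT
Act12	ACT
Act13	ACT
Act14	ACT
Act15	ACT
Act2	ACT
Act3	ACT
Act4	ACT
Act5	ACT
Act6	ACT
Act7	ACT
Act8	ACT
Act9	ACT
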