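substrate_id	gene_symbol	gene_name	p_raw	q	mean_neg	mean_pos	lfc
41_654_666	EPB41	Erythrocyte membrane protein band 4.1	2.7E-03	1.7E-03	9.68	8.82	-0.85
B3AT_39_51	SLC4A1	Solute carrier family 4, anion exchanger, member 1	4.2E-03	3.3E-03	5.34	2.58	-2.76
CD3Z_146_158	CD247	CD247 molecule	6.9E-03	5.0E-03	7.02	5.19	-1.83
CDK2_8_20	CDK2	Cyclin-dependent kinase 2	7.2E-03	6.7E-03	10.99	9.96	-1.02
CRK_214_226	CRK	v-crk sarcoma virus CT10 oncogene homolog	8.8E-03	8.3E-03	6.02	3.24	-2.78
EGFR_1165_1177	EGFR	Epidermal growth factor receptor	1.5E-02	1.0E-02	5.90	4.56	-1.34
EPHA1_774_786	EPHA1	EPH receptor A1	1.6E-02	1.2E-02	9.87	8.82	-1.06
EPHA2_765_777	EPHA2	EPH receptor A2	1.9E-02	1.3E-02	10.25	9.12	-1.13
EPHA7_607_619	EPHA7	EPH receptor A7	2.1E-02	1.5E-02	9.15	8.11	-1.04
EPHB1_771_783	EPHB1	EPH receptor B1	2.2E-02	1.7E-02	9.13	7.97	-1.16
EPHB1_921_933	EPHB1	EPH receptor B1	2.2E-02	1.8E-02	6.53	3.80	-2.73
EPOR_361_373	EPOR	Erythropoietin receptor	2.2E-02	2.0E-02	9.21	8.19	-1.02
EPOR_419_431	EPOR	Erythropoietin receptor	2.6E-02	2.2E-02	8.49	6.87	-1.62
ERBB2_1241_1253	ERBB2	v-erb-b2 erythroblastic leukemia viral oncogene homolog 2	2.7E-02	2.3E-02	6.76	5.22	-1.54
ERBB2_870_882	ERBB2	v-erb-b2 erythroblastic leukemia viral oncogene homolog 2	3.1E-02	2.5E-02	6.83	5.12	-1.70
FES_706_718	FES	Feline sarcoma oncogene	3.1E-02	2.7E-02	10.26	9.18	-1.08
FGFR3_753_765	FGFR3	Fibroblast growth factor receptor 3	3.3E-02	2.8E-02	7.73	6.23	-1.50
INSR_992_1004	INSR	Insulin receptor	3.3E-02	3.0E-02	5.29	3.08	-2.22
JAK2_563_577	JAK2	Janus kinase 2	3.5E-02	3.2E-02	7.79	6.68	-1.12
LCK_387_399	LCK	Lymphocyte-specific protein tyrosine kinase	3.7E-02	3.3E-02	8.68	7.61	-1.07
MK14_173_185	MAPK14	Mitogen-activated protein kinase 14	3.8E-02	3.5E-02	5.11	3.17	-1.94
ODBA_340_352	BCKDHA	Branched chain keto acid dehydrogenase E1, alpha polypeptide	4.0E-02	3.7E-02	5.78	2.93	-2.85
P85A_600_612	PIK3R1	Phosphoinositide-3-kinase, regulatory subunit 1 (alpha)	4.3E-02	3.8E-02	10.50	9.17	-1.32
PAXI_24_36	PXN	Paxillin	4.3E-02	4.0E-02	10.38	9.02	-1.37
PDPK1_369_381	PDPK1	3-phosphoinositide-dependent protein kinase-1	4.6E-02	4.2E-02	8.52	7.75	-0.77
RET_1022_1034	RET	Ret proto-oncogene	4.7E-02	4.3E-02	9.82	8.84	-0.98
STAT4_714_726	STAT4	Signal transducer and activator of transcription 4	4.7E-02	4.5E-02	6.05	3.90	-2.15
VGFR1_1040_1052	FLT1	FMS-related tyrosine kinase-1	4.7E-02	4.7E-02	5.54	3.62	-1.92
VGFR2_1046_1058	KDR	Kinase insert domain receptor	4.8E-02	4.8E-02	5.17	2.71	-2.46
VGFR2_989_1001	KDR	Kinase insert domain receptor	4.8E-02	5.0E-02	9.53	8.48	-1.05
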