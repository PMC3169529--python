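trait	platform	biofluid	snp	snp_pct	snp_lo	snp_hi	familial_pct	familial_lo	familial_hi	indiv_env_pct	indiv_visit_pct	common_visit_pct	replicated
TMAu	NMR	urine	rs7072216	64	55	72	15	5	24	2	16	4	1
N-ACu	NMR	urine	rs9309473	53	42	62	14	4	25	3	28	3	1
BAIBu	NMR	urine	rs37369	40	27	53	44	32	57	1	8	7	1
DMAp	NMR	plasma	rs6584194	40	23	57	22	3	46	14	11	13	1
PC aa C36:3/PC aa C36:4	Biocrates	plasma	rs174547	35	23	46	12	1	25	22	26	5	1
C3/C4	Biocrates	plasma	rs2014355	29	16	40	51	37	65	5	14	1	1
C12/C10	Biocrates	plasma	rs211718	15	5	27	62	47	76	5	14	4	1
C9/C10:2	Biocrates	plasma	rs2286963	22	10	35	26	5	45	9	38	5	1
PC aa C40:3/PC aa C42:5	Biocrates	plasma	rs9393903	12	3	24	32	6	55	41	10	6	1
Gly-PTC/PC ae C38:2	Biocrates	plasma	rs2216405	13	4	24	32	10	52	22	28	4	1
PC ae C32:1/PC ae C34:1	Biocrates	plasma	rs7156144	7	1	17	27	5	49	13	42	11	1
PC ae C38:1/PC aa C28:1	Biocrates	plasma	rs11158519	7	1	16	66	51	79	22	3	1	1
SM (OH) C24:1/SM C16:0	Biocrates	plasma	rs168622	7	0	17	44	22	64	28	19	2	1
C14:1-OH/C10	Biocrates	plasma	rs8396	2	0	9	74	52	90	5	16	3	1
C0	Biocrates	plasma	rs7094971	9	2	17	41	23	58	8	39	3	1
PC ae C44:5/PC ae C42:5	Biocrates	plasma	rs2046813	8	1	19	61	41	76	18	11	2	1
C14/C16:1	Biocrates	plasma	rs603424	9	1	20	47	14	73	14	21	10	0
Val-PTC/C5	Biocrates	plasma	rs272889	9	2	19	40	18	58	7	40	3	1
Orn-PTC/Ser-PTC	Biocrates	plasma	rs541503	2	0	7	44	15	68	30	13	12	0
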