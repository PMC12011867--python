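pt	n	ror	lo	hi	prr	chi2	ic2sd	eb05
malignant neoplasm progression	104	36.25	29.75	44.18	34.33	3367.13	4.41	28.14
product use in unapproved indication	63	9.38	7.29	12.05	9.1	455.83	2.65	7.08
anemia	32	5.4	3.81	7.66	5.33	112.79	1.73	3.76
neutropenia	31	7.61	5.34	10.86	7.51	175.17	2.13	5.26
adverse event	30	10.68	7.45	15.32	10.53	259.05	2.49	7.34
neuropathy peripheral	26	9.3	6.32	13.7	9.19	190.0	2.26	6.24
inappropriate schedule of product administration	22	4.62	3.03	7.03	4.58	61.66	1.38	3.01
skin disorder	22	21.86	14.35	33.28	21.62	432.49	2.9	14.19
neutrophil count decreased	22	18.24	11.98	27.77	18.04	354.05	2.77	11.84
myelosuppression	19	26.28	16.72	41.31	26.03	457.12	2.88	16.55
febrile neutropenia	19	9.54	6.07	14.99	9.45	143.74	2.08	6.01
hypothyroidism	14	14.67	8.67	24.81	14.57	176.88	2.19	8.6
drug eruption	14	26.61	15.72	45.02	26.42	342.18	2.54	15.6
immune-mediated enterocolitis	13	164.0	94.91	283.4	162.9	2080.12	2.92	93.74
female genital tract fistula	12	241.76	136.73	427.47	240.25	2835.64	2.82	134.77
renal impairment	12	4.72	2.68	8.33	4.7	34.99	1.07	2.66
intestinal perforation	12	35.12	19.9	61.97	34.9	394.79	2.47	19.76
platelet count decreased	12	3.63	2.06	6.41	3.62	22.74	0.79	2.05
urogenital fistula	12	1860.84	1036.36	3341.22	1849.18	20836.24	2.86	968.11
colitis	11	9.99	5.52	18.07	9.94	88.44	1.67	5.49
immune-mediated endocrinopathy	10	3595.38	1861.09	6945.79	3576.6	31817.91	2.53	1647.98
hepatic function abnormal	9	8.06	4.19	15.52	8.03	55.39	1.32	4.17
transfusion	7	21.19	10.09	44.53	21.12	134.1	1.56	10.05
proteinuria	7	12.42	5.91	26.09	12.38	73.2	1.33	5.89
immune-mediated hepatic disorder	7	153.84	73.1	323.77	153.28	1053.48	1.91	72.45
immune-mediated hypothyroidism	6	254.18	113.65	568.47	253.39	1495.28	1.68	112.32
erythema multiforme	6	20.66	9.27	46.06	20.6	111.83	1.35	9.23
eastern cooperative oncology group performance status worsened	6	165.59	74.13	369.89	165.07	972.95	1.66	73.48
cytokine release syndrome	6	13.49	6.05	30.06	13.45	69.11	1.18	6.03
cervix carcinoma recurrent	5	1241.29	506.6	3041.5	1238.05	5926.99	1.37	484.58
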