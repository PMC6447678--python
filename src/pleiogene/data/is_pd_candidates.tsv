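method	chrom	gene	p_is	p_pd	chi2	meta_p
vegas	4	GAK	3.55E-02	2.00E-06	32.92	1.24E-06
vegas	4	MMRN1	3.38E-02	3.70E-05	27.18	1.82E-05
vegas	1	GPX7	2.00E-03	9.52E-04	26.34	2.70E-05
vegas	14	NUDT14	3.56E-04	7.40E-03	25.69	3.65E-05
vegas	2	LBH	1.57E-03	2.13E-03	25.22	4.55E-05
vegas	5	ZCCHC10	6.30E-03	6.75E-04	24.74	5.68E-05
vegas	22	P2RX6	6.23E-03	1.30E-03	23.45	1.03E-04
vegas	7	DENND2A	2.42E-03	7.78E-03	21.76	2.24E-04
vegas	2	LOC101928455	2.69E-03	9.90E-03	21.07	3.07E-04
setscreen	14	NUDT14	3.58E-04	7.82E-03	25.57	3.86E-05
setscreen	3	PARP3	2.30E-03	1.71E-03	24.89	5.28E-05
setscreen	1	GPX7	2.50E-03	2.49E-03	23.98	8.08E-05
setscreen	5	ZCCHC10	7.22E-03	8.75E-04	23.94	8.19E-05
setscreen	1	MEX3A	4.54E-04	4.20E-02	21.73	2.26E-04
setscreen	7	DENND2A	5.51E-03	8.30E-03	19.99	5.03E-04
setscreen	1	CRNN	2.37E-02	2.48E-03	19.48	6.31E-04
setscreen	19	RGS9BP	3.74E-03	1.57E-02	19.48	6.31E-04
setscreen	2	LBH	1.01E-02	7.01E-03	19.12	7.44E-04
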