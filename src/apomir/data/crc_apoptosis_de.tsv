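gene	tumor_mean	normal_mean	fold_change	raw_p	adjusted_p
SPTA1	0.73	2.32	0.32	1.73E-06	3.03E-06
MAPK10	9.26	28.10	0.33	8.93E-34	1.48E-32
TUBAL3	3.06	8.27	0.37	4.43E-16	1.44E-15
CSF2RB	27.82	73.57	0.38	7.06E-38	1.88E-36
BCL2	24.42	62.11	0.39	3.73E-39	1.24E-37
FOS	185.52	453.52	0.41	9.65E-31	1.07E-29
CASP12	0.42	0.94	0.45	7.00E-04	1.02E-03
NTRK1	1.10	2.43	0.45	3.24E-07	5.98E-07
ITPR1	57.21	109.94	0.52	5.07E-36	9.63E-35
FAS	28.16	50.95	0.55	2.75E-24	1.66E-23
CASP10	65.13	111.98	0.58	5.20E-32	6.92E-31
PIK3CD	27.33	46.48	0.59	9.96E-22	4.42E-21
TUBA8	3.28	5.46	0.60	8.69E-09	1.75E-08
IL3RA	2.21	3.59	0.62	2.82E-03	3.95E-03
CASP7	59.81	96.30	0.62	1.52E-24	1.01E-23
TUBA3E	0.42	0.68	0.62	9.17E-03	1.22E-02
CTSS	113.76	180.97	0.63	1.46E-23	7.76E-23
FASLG	1.07	1.70	0.63	4.96E-03	6.74E-03
BCL2L11	56.19	88.47	0.64	1.23E-23	6.82E-23
LMNA	245.65	386.57	0.64	3.99E-20	1.66E-19
MAP3K14	33.86	51.73	0.65	1.46E-24	1.01E-23
BIRC3	79.53	120.36	0.66	1.83E-14	5.17E-14
EIF2AK3	52.04	78.19	0.67	3.08E-23	1.57E-22
MAPK3	62.34	92.73	0.67	9.12E-19	3.37E-18
TNFSF10	48.33	71.22	0.68	1.22E-12	3.07E-12
CFLAR	203.49	290.53	0.70	2.89E-29	2.96E-28
CTSW	2.82	3.99	0.71	4.76E-04	7.11E-04
RIPK1	49.35	69.68	0.71	1.19E-19	4.53E-19
ERN1	27.13	38.17	0.71	4.23E-11	9.87E-11
BAD	13.13	18.42	0.71	1.38E-11	3.28E-11
CAPN2	244.01	340.39	0.72	1.09E-22	5.38E-22
CASP9	13.05	17.74	0.74	1.52E-08	3.01E-08
TP53AIP1	0.61	0.81	0.75	1.59E-01	1.87E-01
TNFRSF1A	90.65	118.74	0.76	4.32E-20	1.74E-19
ATM	239.32	312.70	0.77	4.82E-16	1.52E-15
DAB2IP	144.00	186.15	0.77	1.71E-14	4.95E-14
MCL1	615.27	794.46	0.77	3.54E-14	9.82E-14
CYCS	95.12	122.36	0.78	1.03E-10	2.35E-10
NFKBIA	58.77	75.03	0.78	1.13E-07	2.17E-07
AKT3	41.45	52.56	0.79	2.51E-05	4.28E-05
CTSF	7.12	8.89	0.80	1.10E-02	1.44E-02
BAK1	20.05	24.24	0.83	2.77E-05	4.60E-05
CTSD	270.28	324.99	0.83	4.20E-07	7.66E-07
BIRC2	81.92	98.12	0.83	6.71E-10	1.44E-09
TRADD	25.11	28.92	0.87	2.47E-03	3.53E-03
ITPR2	221.72	255.25	0.87	3.28E-03	4.55E-03
GADD45G	2.79	3.18	0.88	2.07E-01	2.39E-01
RAF1	131.53	147.29	0.89	5.78E-07	1.04E-06
TRAF1	46.52	51.87	0.90	1.55E-02	1.98E-02
KRAS	107.64	117.88	0.91	1.65E-02	2.09E-02
MAP2K2	69.97	75.76	0.92	1.47E-02	1.90E-02
NFKB1	77.63	83.98	0.92	7.65E-03	1.03E-02
MAP3K5	68.22	73.59	0.93	3.82E-02	4.71E-02
PIDD	28.99	31.19	0.93	1.08E-01	1.30E-01
PARP3	18.95	20.17	0.94	2.44E-01	2.78E-01
IKBKB	137.36	145.80	0.94	6.63E-02	8.08E-02
APAF1	85.50	90.73	0.94	7.64E-02	9.24E-02
PARP2	20.40	21.49	0.95	3.35E-01	3.68E-01
SEPT4	6.07	6.38	0.95	5.52E-01	5.78E-01
TNF	1.95	2.04	0.96	7.52E-01	7.58E-01
CASP3	42.94	44.90	0.96	3.39E-01	3.69E-01
CTSC	83.85	87.45	0.96	2.63E-01	2.93E-01
TNFRSF10D	21.48	22.33	0.96	5.20E-01	5.49E-01
TUBA3D	2.86	2.96	0.97	7.43E-01	7.55E-01
PRF1	5.19	5.24	0.99	9.15E-01	9.15E-01
AKT1	153.83	152.34	1.01	7.08E-01	7.24E-01
JUN	214.48	211.03	1.02	7.02E-01	7.24E-01
MAPK8	62.01	60.98	1.02	6.19E-01	6.43E-01
MAPK1	183.50	179.79	1.02	3.53E-01	3.78E-01
MAPK9	65.92	64.12	1.03	4.12E-01	4.39E-01
PIK3R1	154.42	149.09	1.04	3.00E-01	3.32E-01
PIK3R3	35.88	33.87	1.06	2.55E-01	2.87E-01
CASP6	22.61	21.28	1.06	2.10E-01	2.41E-01
GADD45B	12.90	12.05	1.07	3.43E-01	3.71E-01
PDPK1	100.97	93.03	1.09	3.80E-03	5.21E-03
IKBKG	6.91	6.20	1.11	2.04E-01	2.38E-01
PIK3CB	90.89	81.36	1.12	5.56E-04	8.21E-04
RELA	82.20	73.32	1.12	5.56E-06	9.60E-06
CTSZ	123.07	109.77	1.12	2.59E-03	3.66E-03
ITPR3	420.93	374.92	1.12	2.74E-05	4.60E-05
DIABLO	39.85	35.12	1.13	6.78E-05	1.07E-04
CAPN1	187.82	164.50	1.14	1.79E-07	3.41E-07
ENDOG	12.68	11.09	1.14	2.72E-02	3.41E-02
GADD45A	13.07	11.37	1.15	3.07E-02	3.81E-02
AKT2	156.81	135.87	1.15	2.66E-07	4.99E-07
SPTAN1	543.11	467.35	1.16	3.33E-10	7.38E-10
MAP2K1	32.75	28.06	1.17	4.28E-04	6.55E-04
CTSL1	20.11	17.18	1.17	1.18E-02	1.53E-02
CHUK	44.48	37.81	1.18	4.50E-04	6.80E-04
HTRA2	19.32	16.19	1.19	5.92E-05	9.61E-05
XIAP	187.63	156.09	1.20	8.16E-13	2.13E-12
PIK3CA	67.11	55.23	1.22	6.77E-07	1.20E-06
FADD	14.64	12.03	1.22	7.19E-04	1.04E-03
BAX	36.23	29.75	1.22	1.59E-04	2.49E-04
CASP8	70.64	57.92	1.22	3.90E-09	8.11E-09
DFFB	16.02	13.07	1.23	1.87E-04	2.89E-04
ATF4	130.84	105.67	1.24	8.92E-13	2.28E-12
BCL2A1	2.01	1.61	1.25	1.59E-01	1.87E-01
DAXX	35.66	28.09	1.27	3.63E-10	7.92E-10
BID	35.72	27.95	1.28	2.19E-09	4.63E-09
TNFRSF10A	37.99	28.64	1.33	2.17E-08	4.25E-08
PIK3R2	72.83	54.55	1.34	1.32E-18	4.73E-18
DDIT3	11.07	8.29	1.34	3.01E-05	4.93E-05
ACTB	2123.22	1584.09	1.34	3.58E-28	3.18E-27
NRAS	104.64	76.74	1.36	3.26E-15	9.64E-15
TRAF2	40.20	29.46	1.36	8.02E-13	2.13E-12
PARP1	109.63	79.73	1.37	5.66E-16	1.75E-15
EIF2S1	70.00	50.27	1.39	6.06E-16	1.83E-15
DFFA	86.27	61.10	1.41	2.64E-24	1.66E-23
TUBA1A	27.86	19.65	1.42	8.44E-09	1.73E-08
CASP2	124.24	87.36	1.42	9.53E-25	7.04E-24
CTSB	513.97	360.55	1.43	2.50E-22	1.19E-21
ACTG1	1209.84	823.20	1.47	6.71E-29	6.38E-28
CTSH	76.75	51.92	1.48	5.16E-14	1.40E-13
HRAS	18.52	12.37	1.50	3.52E-12	8.66E-12
PARP4	340.90	226.33	1.51	2.95E-26	2.45E-25
TNFRSF10B	135.53	89.65	1.51	3.45E-21	1.48E-20
AIFM1	41.19	27.11	1.52	4.56E-17	1.55E-16
CTSK	48.58	31.12	1.56	8.29E-12	2.00E-11
TNFRSF10C	3.54	2.10	1.69	6.25E-05	1.00E-04
TUBA4A	33.42	19.75	1.69	3.16E-22	1.45E-21
TP53	105.07	59.63	1.76	3.25E-24	1.88E-23
BBC3	20.58	11.49	1.79	2.02E-18	7.06E-18
TUBA1B	138.84	76.60	1.81	3.01E-31	3.64E-30
LMNB1	89.36	43.88	2.04	1.01E-36	2.23E-35
TUBA1C	69.89	33.41	2.09	1.39E-32	2.05E-31
PTPN13	69.58	32.80	2.12	4.54E-20	1.78E-19
LMNB2	150.48	68.95	2.18	1.08E-45	7.20E-44
BCL2L1	144.28	64.05	2.25	1.06E-56	1.41E-54
GZMB	4.21	1.49	2.83	2.11E-10	4.77E-10
BIRC5	35.63	11.31	3.15	1.67E-39	7.41E-38
PMAIP1	11.00	3.31	3.32	6.06E-26	4.74E-25
CTSL2	4.38	1.21	3.64	8.07E-17	2.68E-16
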