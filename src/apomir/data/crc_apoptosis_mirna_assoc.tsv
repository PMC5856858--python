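gene	gene_tumor_mean	gene_normal_mean	gene_fold_change	mirna	mirna_tumor_mean	mirna_normal_mean	mirna_fold_change	beta	raw_p	fdr_p	seed_match
BIRC5	35.63	11.31	3.15	hsa-miR-106b-5p	15.90	5.19	3.06	0.23	0.0007	0.0285	1
BIRC5	35.63	11.31	3.15	hsa-miR-1246	629.21	412.81	1.52	0.25	0.0006	0.0257	0
BIRC5	35.63	11.31	3.15	hsa-miR-145-5p	132.97	223.14	0.60	-0.32	<0.0001	0.0102	1
BIRC5	35.63	11.31	3.15	hsa-miR-150-5p	14.90	39.17	0.38	-0.24	0.0003	0.0174	1
BIRC5	35.63	11.31	3.15	hsa-miR-17-5p	61.04	16.38	3.73	0.28	<0.0001	0.0102	1
BIRC5	35.63	11.31	3.15	hsa-miR-195-5p	3.59	12.18	0.29	-0.25	0.0005	0.0226	1
BIRC5	35.63	11.31	3.15	hsa-miR-19b-3p	29.80	10.42	2.86	0.28	<0.0001	0.0102	0
BIRC5	35.63	11.31	3.15	hsa-miR-20a-5p	70.78	17.61	4.02	0.25	0.0004	0.0192	1
BIRC5	35.63	11.31	3.15	hsa-miR-20b-5p	17.65	3.30	5.35	0.28	<0.0001	0.0102	1
BIRC5	35.63	11.31	3.15	hsa-miR-21-3p	22.68	9.89	2.29	0.28	0.0002	0.0136	0
BIRC5	35.63	11.31	3.15	hsa-miR-25-3p	30.05	12.78	2.35	0.31	<0.0001	0.0102	0
BIRC5	35.63	11.31	3.15	hsa-miR-425-5p	11.76	6.97	1.69	0.25	0.0003	0.0174	1
BIRC5	35.63	11.31	3.15	hsa-miR-650	4.51	16.60	0.27	-0.26	0.0002	0.0136	1
BIRC5	35.63	11.31	3.15	hsa-miR-93-5p	41.72	15.20	2.74	0.31	<0.0001	0.0102	1
CSF2RB	27.82	73.57	0.38	hsa-miR-1203	1.76	2.83	0.62	0.23	0.0011	0.0497	1
CSF2RB	27.82	73.57	0.38	hsa-miR-124-3p	0.90	2.40	0.38	0.25	0.0005	0.037	1
CSF2RB	27.82	73.57	0.38	hsa-miR-150-5p	14.90	39.17	0.38	0.30	<0.0001	0.0102	1
CSF2RB	27.82	73.57	0.38	hsa-miR-2117	1.50	4.09	0.37	0.28	0.0003	0.0244	0
CSF2RB	27.82	73.57	0.38	hsa-miR-3124-5p	1.37	2.27	0.60	0.28	<0.0001	0.0102	0
CSF2RB	27.82	73.57	0.38	hsa-miR-4315	0.21	2.62	0.08	0.23	0.0008	0.0497	0
CSF2RB	27.82	73.57	0.38	hsa-miR-4469	1.11	2.41	0.46	0.22	0.0011	0.0497	0
CSF2RB	27.82	73.57	0.38	hsa-miR-525-5p	1.56	2.53	0.62	0.22	0.001	0.0497	0
CSF2RB	27.82	73.57	0.38	hsa-miR-650	4.51	16.60	0.27	0.37	<0.0001	0.0102	1
CSF2RB	27.82	73.57	0.38	hsa-miR-92a-3p	121.60	41.18	2.95	-0.24	0.0009	0.0497	1
TNFRSF10B	135.53	89.65	1.51	hsa-miR-196b-5p	17.89	5.53	3.24	-0.25	0.0003	0.0488	1
TNFRSF10B	135.53	89.65	1.51	hsa-miR-3124-5p	1.37	2.27	0.60	-0.26	0.0003	0.0488	0
TUBA1B	138.84	76.60	1.81	hsa-miR-150-5p	14.90	39.17	0.38	-0.25	<0.0001	0.0163	0
TUBA1B	138.84	76.60	1.81	hsa-miR-195-5p	3.59	12.18	0.29	-0.28	0.0002	0.0181	0
CTSK	48.58	31.12	1.56	hsa-miR-193b-3p	9.12	5.42	1.68	0.26	0.0003	0.0271	0
CTSK	48.58	31.12	1.56	hsa-miR-199a-3p	44.83	22.53	1.99	0.35	<0.0001	0.0102	0
CTSK	48.58	31.12	1.56	hsa-miR-199a-5p	20.18	9.28	2.17	0.33	<0.0001	0.0102	0
CTSK	48.58	31.12	1.56	hsa-miR-199b-5p	4.69	1.53	3.07	0.34	<0.0001	0.0102	0
CTSK	48.58	31.12	1.56	hsa-miR-214-3p	13.24	6.13	2.16	0.38	<0.0001	0.0102	0
CTSK	48.58	31.12	1.56	hsa-miR-934	4.36	0.94	4.66	0.43	<0.0001	0.0102	0
ITPR1	57.21	109.94	0.52	hsa-miR-150-5p	14.90	39.17	0.38	0.34	<0.0001	0.0271	0
ITPR1	57.21	109.94	0.52	hsa-miR-650	4.51	16.60	0.27	0.33	<0.0001	0.0271	1
CTSS	113.76	180.97	0.63	hsa-miR-20b-5p	17.65	3.30	5.35	-0.25	0.0003	0.0488	1
CTSS	113.76	180.97	0.63	hsa-miR-3923	0.29	1.66	0.18	-0.28	0.0002	0.0488	0
CTSS	113.76	180.97	0.63	hsa-miR-501-3p	7.07	2.95	2.39	-0.29	<0.0001	0.0407	1
CASP7	59.81	96.30	0.62	hsa-miR-221-3p	13.53	4.12	3.28	-0.32	<0.0001	0.0407	0
CASP7	59.81	96.30	0.62	hsa-miR-29b-3p	24.31	9.83	2.47	-0.30	<0.0001	0.0407	1
BCL2L1	144.28	64.05	2.25	hsa-miR-92a-3p	121.60	41.18	2.95	0.34	<0.0001	0.0407	0
PIK3CD	27.33	46.48	0.59	hsa-miR-150-5p	14.90	39.17	0.38	0.35	<0.0001	0.0271	1
PIK3CD	27.33	46.48	0.59	hsa-miR-650	4.51	16.60	0.27	0.31	<0.0001	0.0271	0
BCL2	24.42	62.11	0.39	hsa-miR-150-5p	14.90	39.17	0.38	0.34	<0.0001	0.0203	1
BCL2	24.42	62.11	0.39	hsa-miR-195-5p	3.59	12.18	0.29	0.24	0.0003	0.0488	1
BCL2	24.42	62.11	0.39	hsa-miR-203a	12.52	3.70	3.38	-0.27	<0.0001	0.0203	1
BCL2	24.42	62.11	0.39	hsa-miR-650	4.51	16.60	0.27	0.38	<0.0001	0.0203	1
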