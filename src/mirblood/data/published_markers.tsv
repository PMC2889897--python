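miRNA	median melanoma	median normal	fold change	wmw adjp	ttest adjp	limma adjp	AUC
hsa-miR-452*	189.7	633.3	0.3	0	0.00046	0	0.99
hsa-miR-216a	89.1	197.3	0.5	0.000001	1.7E-05	0.000039	0.98
hsa-miR-186	206.5	26.2	7.9	0.000001	0	0	0.97
hsa-let-7d*	178.6	37.7	4.7	0.000001	0	0	0.96
hsa-miR-17*	433.5	941.8	0.5	0.000001	0	0	0.96
hsa-miR-646	150.9	350.6	0.4	0.000001	0.00038	0	0.96
hsa-miR-217	86.3	183.8	0.5	0.000001	0.00055	0.000003	0.96
hsa-miR-621	178.6	486.7	0.4	0.000001	0.00011	0	0.95
hsa-miR-517*	109.9	230.8	0.5	0.000001	0.00022	0	0.95
hsa-miR-99a	217.3	85	2.6	0.000002	0	0	0.95
hsa-miR-664	557	173	3.2	0.000002	0	0	0.94
hsa-miR-593*	175.4	356.7	0.5	0.000002	0.00027	0	0.94
hsa-miR-18a*	397.4	135	2.9	0.000002	0	0	0.94
hsa-miR-145	358	94.6	3.8	0.000002	0	0	0.94
hsa-miR-1280	6779.6	2676.2	2.5	0.000002	0	0	0.93
hsa-let-7i*	122.8	281.4	0.4	0.000003	0.00045	0	0.93
hsa-miR-422a	279.2	104.5	2.7	0.000004	0	0	0.92
hsa-miR-330-3p	213.1	443.2	0.5	0.000004	0.00052	0	0.92
hsa-miR-767-5p	107.1	232.4	0.5	0.000004	0.00022	0.000001	0.92
hsa-miR-183*	195.9	87.7	2.2	0.000004	1E-06	0	0.92
hsa-miR-1249	144.8	46.1	3.1	0.000004	0	0.000004	0.92
hsa-miR-20b	2163.5	5665.8	0.4	0.000004	2E-06	0.000001	0.92
hsa-miR-509-3-5p	157	371.4	0.4	0.000004	0.00046	0	0.92
hsa-miR-519b-5p	72.5	155.1	0.5	0.000004	2.9E-05	0.000398	0.92
hsa-miR-362-3p	449	167.8	2.7	0.000004	4E-06	0	0.92
hsa-miR-501-5p	106.5	27.8	3.8	0.000004	0	0.000002	0.92
hsa-miR-378*	103.7	29.4	3.5	0.000004	0	0.000002	0.92
hsa-miR-365	160.5	65.1	2.5	0.000006	0	0.000001	0.91
hsa-miR-151-3p	999	422.6	2.4	0.000006	1E-06	0	0.91
hsa-miR-342-5p	196.8	92.1	2.1	0.000008	1E-06	0.000003	0.91
hsa-miR-328	175.4	32.3	5.4	0.000008	0	0.000001	0.9
hsa-miR-181a-2*	154.8	64.7	2.4	0.000016	4E-06	0.000004	0.89
hsa-miR-518e*	88.1	196.4	0.4	0.000019	0.00045	0.000586	0.89
hsa-miR-362-5p	245.4	119.5	2.1	0.000023	8E-06	0.000001	0.88
hsa-miR-584	198.2	46.9	4.2	0.000023	1.5E-05	0.000008	0.88
hsa-miR-550*	808.5	313.8	2.6	0.000024	2.6E-05	0.000003	0.88
hsa-miR-30a	682.9	334.8	2	0.000027	4E-06	0.000002	0.88
hsa-miR-221*	54.3	113.8	0.5	0.000029	0.00011	0.00039	0.88
hsa-miR-361-3p	263.9	99	2.7	0.000033	2E-06	0.000003	0.88
hsa-miR-625	185.8	63.3	2.9	0.000037	1.7E-05	0.000038	0.87
hsa-miR-146a	326.8	161.8	2	0.000037	3.9E-05	0.000003	0.87
hsa-miR-214	172.3	383.4	0.4	0.000042	0.00038	0.000001	0.87
hsa-miR-106b	8639.8	18881	0.5	0.000044	8.5E-05	0.000019	0.87
hsa-miR-18a	1060.8	2560	0.4	0.000053	0.00074	0.000013	0.86
hsa-miR-30e*	101.7	47.8	2.1	0.000022	5E-06	0.000098	0.86
hsa-miR-125a-5p	370.8	147.4	2.5	0.000059	3.3E-05	0.000001	0.86
hsa-miR-142-3p	105.3	2	53	0.000082	1.7E-05	0.000009	0.85
hsa-miR-107	725.8	1938.9	0.4	0.000092	0.00097	0.000034	0.85
hsa-miR-20a	3254.3	7282.8	0.4	0.000134	0.00016	0.000062	0.84
hsa-miR-22*	117.7	45	2.6	0.000193	3.7E-05	0.000138	0.83
hsa-miR-199a-5p	551.4	267.9	2.1	0.000201	0.00066	0.000042	0.83
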