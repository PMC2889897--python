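miRNA	fold change qRT-PCR	fold change microarray
hsa-miR-106b	0.54	1.09
hsa-miR-107	0.70	0.68
hsa-miR-1280	1.15	3.01
hsa-miR-151-3p	1.02	2.05
hsa-miR-17*	0.59	0.60
hsa-miR-18a	0.40	0.42
hsa-miR-199a-5p	1.08	2.77
hsa-miR-20a	0.41	0.58
hsa-miR-20b	0.48	0.88
hsa-miR-30a	0.78	1.14
hsa-miR-362-3p	0.98	2.07
hsa-miR-550*	0.65	1.02
hsa-miR-664	0.65	0.83
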