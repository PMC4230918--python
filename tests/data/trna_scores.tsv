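orthology	gene	NS	A	B	C
K14218	tRNA-Ala	68	85.13	80.86	95.21
K14219	tRNA-Arg	90	84.58	81.98	91.86
K14220	tRNA-Asn	46	86.18	80.83	89.33
K14221	tRNA-Asp	55	96.54	91.00	91.11
K14222	tRNA-Cys	24	91.27	86.26	93.00
K14223	tRNA-Gln	43	88.20	84.83	86.89
K14224	tRNA-Glu	65	88.22	89.53	92.00
K14225	tRNA-Gly	87	86.00	83.07	87.65
K14226	tRNA-His	33	79.80	79.97	93.64
K14227	tRNA-Ile	59	89.39	89.46	94.36
K14228	tRNA-Leu	91	88.85	90.53	91.74
K14229	tRNA-Lys	69	86.94	93.94	88.64
K14230	tRNA-Met	38	86.56	91.20	90.71
K14231	tRNA-Phe	44	85.80	86.03	89.64
K14232	tRNA-Pro	48	76.52	83.81	85.63
K14233	tRNA-Ser	84	89.88	90.99	95.30
K14234	tRNA-Thr	66	79.89	79.23	94.35
K14235	tRNA-Trp	33	92.94	90.08	88.09
K14236	tRNA-Tyr	41	88.55	86.82	92.96
K14237	tRNA-Val	74	83.73	85.95	95.69
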