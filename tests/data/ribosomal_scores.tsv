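orthology	gene	NS	A	B	C
K01982	Large subunit ribosomal RNA	65	75.33	93.57	81.04
K01979	Small subunit ribosomal RNA	64	76.99	87.50	81.13
K02963	Ribosomal protein S18	22	81.19	79.31	84.85
K02964	Ribosomal protein S18e	27	89.18	90.45	96.32
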