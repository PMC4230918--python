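orthology	gene	NS	A	B	C
K01872	Alanyl-tRNA synthetase	24	85.11	80.07	84.71
K01887	Arginyl-tRNA synthetase	23	76.14	93.67	79.31
K01893	Asparaginyl-tRNA synthetase	32	89.44	91.00	85.96
K01876	Aspartyl-tRNA synthetase	29	87.88	91.10	86.28
K01883	Cysteinyl-tRNA synthetase	25	75.75	81.38	84.75
K01886	Glutaminyl-tRNA synthetase	16	76.87	80.29	85.32
K01885	Glutamyl-tRNA synthetase	22	93.44	89.99	90.27
K01880	Glycyl-tRNA synthetase	18	80.30	82.07	68.41
K01892	Histidyl-tRNA synthetase	23	82.39	80.93	93.00
K01870	Isoleucyl-tRNA synthetase	29	73.20	84.47	85.99
K01869	Leucyl-tRNA synthetase	28	84.43	80.77	78.68
K04567	Lysyl-tRNA synthetase, class II	24	72.61	83.08	75.03
K01874	Methionyl-tRNA synthetase	30	87.02	90.63	93.46
K01889	Phenylalanyl-tRNA synthetase	30	82.94	77.28	91.94
K01890	Phenylalanyl-tRNA synthetase	16	93.35	77.13	77.84
K01881	Prolyl-tRNA synthetase	23	84.01	87.98	79.11
K01875	Seryl-tRNA synthetase	30	74.98	73.18	90.28
K01868	Threonyl-tRNA synthetase	35	89.14	73.77	78.12
K01867	Tryptophanyl-tRNA synthetase	28	82.83	84.23	81.47
K01866	Tyrosyl-tRNA synthetase	30	79.04	73.57	87.78
K01873	Valyl-tRNA synthetase	25	78.60	86.56	78.30
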