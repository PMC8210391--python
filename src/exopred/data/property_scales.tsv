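scale	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y	source
average_flexibility	0.357	0.346	0.511	0.497	0.314	0.544	0.323	0.462	0.466	0.365	0.295	0.463	0.509	0.493	0.529	0.507	0.444	0.386	0.305	0.420	Bhaskaran & Ponnuswamy (1988) average flexibility index
residue_volume	88.3	112.4	110.8	140.5	189.0	60.0	152.6	168.5	175.6	168.5	162.2	125.1	122.2	148.7	181.2	88.7	118.2	141.4	227.0	193.0	Goldsack & Chalifoux (1973) residue volume
relative_mutability	100	20	106	102	41	49	66	96	56	40	94	134	56	93	65	120	97	74	18	41	Dayhoff et al. (1978) relative mutability
net_charge	0	0	-1	-1	0	0	0	0	1	0	0	0	0	0	1	0	0	0	0	0	Klein et al. (1984) net charge at pH 7
side_chain_interaction	0.92	1.16	0.48	0.61	1.25	0.61	0.93	1.81	0.70	1.30	1.19	0.60	0.68	0.66	0.93	0.55	0.63	1.49	1.54	1.47	Oobatake & Ooi optimized side-chain interaction parameter
polarity	8.1	5.5	13.0	12.3	5.2	9.0	10.4	5.2	11.3	4.9	5.7	11.6	8.0	10.5	10.5	9.2	8.6	5.9	5.4	6.2	Grantham (1974) polarity
designed_helix_propensity	-0.27	0.13	0.10	-0.33	0.01	0.39	0.05	-0.10	-0.26	-0.33	-0.25	0.15	1.00	-0.17	-0.18	0.10	0.07	0.06	-0.01	0.03	Koehl & Levitt (1999) alpha-helix propensity from designed sequences
designed_sheet_propensity	0.15	-0.08	0.26	0.10	-0.23	0.33	0.02	-0.35	0.06	-0.10	-0.05	0.18	0.85	0.05	0.03	0.00	-0.16	-0.40	-0.19	-0.24	Koehl & Levitt (1999) beta-sheet propensity from designed sequences
amphiphilicity	0.00	0.00	0.00	1.27	0.04	0.00	1.45	0.00	3.67	0.00	0.00	0.00	0.00	1.25	2.45	0.00	0.00	0.00	6.93	5.06	Mitaku et al. (2002) amphiphilicity index
modified_kyte_doolittle	1.10	2.50	-3.60	-3.20	2.80	-0.64	-3.20	4.50	-4.11	3.80	1.90	-3.50	-1.90	-3.68	-5.10	-0.50	-0.70	4.20	-0.46	-1.30	Juretic et al. (1998) modified Kyte-Doolittle hydrophobicity
aromaticity	0	0	0	0	1	0	0	0	0	0	0	0	0	0	0	0	0	0	1	1	binary indicator for aromatic side chains (F, W, Y)
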