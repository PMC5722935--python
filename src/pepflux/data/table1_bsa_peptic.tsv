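# Reference annotation table for the 43 peptides identified in a BSA peptic
# hydrolysate and its ultrafiltration permeates (experimental literature data,
# transcribed; bioactivity scores are neural-network predictions consumed as
# data). mw is the singly protonated monoisotopic mass [M+H]+ in Da; charges
# in elementary units; group: A=acid (pI<5), B=basic (pI>8), N=neutral.
mw	preceding	sequence	following	charge_ph2	charge_ph10	group	gravy	bioactivity
592.30	F	YAPEL	L	0.90	-2.50	A	-0.16	0.38
471.28	A	PELL	Y	0.90	-2.00	A	0.63	0.34
639.28	E	ACFAVE	G	0.90	-3.00	A	0.87	0.34
634.34	A	PELLY	Y	0.90	-2.50	A	0.24	0.32
596.29	E	YEATL	E	0.90	-2.50	A	0.02	0.13
424.21	Y	LYE	I	0.90	-2.50	A	-0.33	0.11
389.20	E	EQL	K	0.90	-2.00	A	-1.07	0.07
483.21	E	YEAT	L	0.90	-2.50	A	-0.93	0.06
362.19	E	LTE	F	0.90	-2.00	A	-0.13	0.04
346.20	F	VEV	T	0.90	-2.00	A	1.63	0.02
1059.58	E	IARRHPYF	Y	3.90	0.50	B	-0.75	0.73
731.42	A	WSVARL	S	1.90	0.00	B	0.60	0.68
517.28	L	HTLF	G	1.90	-1.00	B	0.68	0.59
401.29	L	LRL	A	1.90	0.00	B	1.03	0.56
1081.57	L	SQKFPKAEF	V	2.90	-1.00	B	-1.09	0.53
1075.52	Y	YANKYNGVF	Q	1.90	-1.50	B	-0.57	0.45
1122.65	L	PKLKPDPNTL	C	2.90	-1.00	B	-1.27	0.43
1238.58	L	YYANKYNGVF	Q	1.90	-2.00	B	-0.64	0.43
825.45	E	TYVPKAF	D	1.90	-1.00	B	0.19	0.30
1107.53	E	YSRRHPEY	A	3.90	-1.00	B	-2.59	0.28
550.33	L	IVRY	T	1.90	-0.50	B	0.73	0.20
893.48	P	VSEKVTKC	C	2.90	-2.00	B	-0.24	0.10
478.27	L	KTVM	E	1.90	-0.50	B	0.38	0.09
801.52	Q	IKKQTAL	V	2.90	0.00	B	-0.27	0.09
1051.62	L	LKHKPKATE	E	4.90	-0.50	B	-1.68	0.08
838.48	E	HVKLVNE	L	2.90	-1.50	B	-0.27	0.05
1546.91	L	IVRYTRKVPQVST	P	3.90	1.00	B	-0.34	0.05
414.20	L	FTF	H	0.90	-1.00	N	1.63	0.97
350.21	L	IAF	S	0.90	-1.00	N	3.03	0.82
514.23	E	YGFQ	N	0.90	-1.50	N	-0.60	0.79
358.27	W	LLL	L	0.90	-1.00	N	3.80	0.57
336.19	F	VAF	V	0.90	-1.00	N	2.90	0.56
423.22	L	GLAY	P	0.90	-1.50	N	0.98	0.46
330.20	T	PTL	V	0.90	-1.00	N	0.50	0.35
713.42	F	AVEGPKL	V	1.90	-1.50	N	0.06	0.30
474.27	D	RADL	A	1.90	-1.00	N	-0.60	0.26
382.20	D	YLS	L	0.90	-1.50	N	0.57	0.24
940.48	E	TYVPKAFD	E	1.90	-2.00	N	-0.28	0.17
488.31	Y	AVSVL	L	0.90	-1.00	N	2.64	0.12
700.42	L	LPKIET	M	1.90	-1.50	N	-0.23	0.10
417.27	A	VSVL	L	0.90	-1.00	N	2.85	0.08
688.43	F	VEVTKL	V	1.90	-1.50	N	0.68	0.05
533.29	L	VVSTQ	T	0.90	-1.00	N	0.68	0.03
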