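site	genome_position	gene_position	codon	aa_change	fronds_pct	turions_pct	Cn	Os	Zm	At	Nt	Sl
5'UTR rps7-1	105389	-	-	-	67	90	?	?	?	T	T	T
atpF	15203	92	cCa	P>L	95	86	+	T	T	+	+	?
intergenic-1	66923	-	-	-	26	23	NA	NA	NA	NA	NA	NA
intergenic-2	67274	-	-	-	16	20	NA	NA	NA	NA	NA	NA
intergenic-3	73142	-	-	-	19	18	NA	NA	NA	NA	NA	NA
intergenic-4	86259	-	-	-	6	6	?	?	?	?	?	?
intergenic-5	106653	-	-	-	92	91	?	T	T	T	T	T
ndhA-1	135335	476	uCa	S>L	91	93	+	+	+	T	T	T
ndhA-2	135281	530	cCa	P>L	87	78	T	T	T	T	T	T
ndhA-3	134193	566	uCa	S>L	29	28	+	?	+	T	T	T
ndhA-4	133807	952	Cct	P>S	93	95	+	T	T	T	?	?
ndhA-5	133695	1064	uCc	S>F	94	95	+	+	+	T	+	?
ndhB-1	104089	149	uCa	S>L	75	69	+	T	T	+	+	+
ndhB-2	103792	446	uCa	S>L	92	91	T	T	T	T	T	T
ndhB-3	103771	467	cCa	P>L	98	97	+	+	+	+	+	+
ndhB-4	103696	542	aCg	T>M	81	82	+	T	T	T	T	T
ndhB-5	103652	586	Cau	H>Y	79	70	+	+	+	+	+	+
ndhB-6	103534	704	uCc	S>F	93	90	+	+	T	T	T	T
ndhB-7	103501	737	cCa	P>L	74	75	+	+	+	T	+	+
ndhB-8 intron	103280	-	-	-	91	89	?	?	?	?	?	?
ndhB-9	102704	830	uCa	S>L	92	96	+	+	+	+	+	+
ndhB-10	102698	836	uCa	S>L	91	96	+	+	T	+	+	+
ndhB-11	102432	1102	Cgc	R>C	100	100	T	T	T	T	T	T
ndhB-12	102341	1193	uCa	S>L	95	95	+	T	T	T	T	T
ndhB-13	102279	1255	Cau	H>Y	97	96	+	T	T	+	T	T
ndhB-14	102233	1301	uCa	S>L	11	8	?	?	?	?	T	T
ndhB-15	102053	1481	cCa	P>L	88	62	+	+	+	+	+	+
ndhC-1	56026	13	Cac	H>Y	75	65	?	?	?	T	T	T
ndhC-2	55728	311	cCa	P>L	18	30	?	T	T	T	T	T
ndhC-3	55716	323	uCa	S>L	62	92	?	T	T	T	T	T
ndhD-1	130160	2	aCg	T>M	83	61	+	T	T	+	+	+
ndhD-2	129488	674	uCa	S>L	95	94	+	T	T	+	+	+
ndhD-3	129284	878	uCa	S>L	88	91	T	+	+	+	T	+
ndhD-4	129215	947	aCa	T>I	97	93	+	T	T	T	T	T
ndhD-5	128969	1193	uCa	S>L	96	95	+	T	T	T	T	T
ndhD-6	128852	1310	uCa	S>L	90	89	+	T	T	T	+	+
ndhF	125342	62	uCa	S>L	87	88	+	+	+	T	T	T
ndhJ-1	54835	10	Cau	H>Y	100	100	?	T	T	NA	?	?
ndhJ-2	54717	128	uCa	S>L	96	95	?	T	T	T	T	T
petL	72275	44	uCa	S>L	96	95	T	T	T	T	T	T
psbF	70715	77	uCu	S>F	51	49	T	T	T	?	T	T
psbJ	70337	71	uCa	S>L	97	99	T	T	T	T	T	T
psbZ	40491	50	uCa	S>L	71	78	?	?	?	+	T	T
rpl2	92708	2	aCg	T>M	44	48	?	+	+	T	T	T
rpl20	74981	308	uCg	S>L	95	94	+	T	+	T	+	?
rpl22	90376	233	uCa	S>L	98	93	?	T	T	T	T	T
rpl23-1	92939	71	uCu	S>F	89	88	+	T	T	T	?	?
rpl23-2	92921	89	uCa	S>L	55	57	+	T	T	?	?	?
rpoA	85276	200	uCu	S>F	7	8	+	T	T	?	?	?
rpoB-1	28650	473	uCg	S>L	100	81	+	?	+	T	+	+
rpoB-2	26691	2432	uCa	S>L	90	85	+	T	T	+	T	+
rpoC1	25833	62	cCa	P>L	88	88	+	T	T	T	+	?
rpoC2-1	20639	2318	uCa	S>L	85	81	?	T	+	T	T	T
rpoC2-2	20579	2378	cCa	P>L	7	6	?	?	?	?	?	?
rps12	105777	221	uCa	S>L	98	98	T	T	T	T	T	+
rps16	5284	143	uCa	S>L	95	92	T	T	T	T	T	T
rps2	18456	134	aCa	T>I	100	100	+	?	+	T	+	?
rps3	90143	30	uuC	I>I	54	43	?	?	?	?	?	?
rps7-2	104732	300	gcC	A>A	35	65	?	?	?	?	?	?
rps8	86875	182	uCa	S>L	90	96	+	+	+	T	T	T
ycf2	98676	5354	uCa	S>L	88	93	T	NA	NA	T	T	T
ycf3-1	49098	63	atC	I>I	70	94	T	T	T	?	?	?
ycf3-2 intron	48447	-	-	-	87	90	?	?	?	T	T	T
ycf3-3	48230	185	aCg	T>M	97	100	+	?	+	T	T	T
ycf3-4	48224	191	cCa	P>L	96	98	+	T	T	T	T	T
ycf3-5	47241	407	uCc	S>F	78	92	+	T	T	T	T	T
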