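mqtl_id	tissue_class	chromosome	bin	ci_start_cM	position_cM	ci_end_cM	ci95_width_cM	flank_left	flank_right	phys_start_mbp	phys_end_mbp
SIR1	stem	1	1.01	48.06	57.39	65.53	18.53	bhlh140	fha1	4.74	5.75
SIR2	stem	1	1.01-02	100.5	112.72	122.33	22.94	php20689	ms26	10.07	14.50
LIR1	leaf	1	1.01-02	80.82	134.13	185.67	106.27	idp4725	tidp6152	6.76	27.39
SIR3	stem	1	1.04	328.75	344.79	357.15	30.28	pza02114	umc2532	54.84	65.48
KIR1	kernel	1	1.04-06	315.64	430.99	545.00	231.05	umc1452	uaz15	53.17	191.13
LIR2	leaf	1	1.05-06	471.83	491.72	511.15	40.19	umc1395	bnlg1041	164.55	183.90
SIR4	stem	1	1.06	522.07	526.93	530.81	9.25	idp7408	csu256(hsp90)	183.77	188.13
LIR3	leaf	1	1.06-07	601.80	610.06	617.09	16.21	gpm136	umc2237	198.10	200.72
SIR5	stem	1	1.07	667.33	674.08	678.25	11.30	idp4855	rz698a(ppy)	210.52	219.19
KIR2	kernel	1	1.09-10	866.11	899.80	929.46	64.96	agrc362b	tlk1	262.07	276.36
LIR4	leaf	1	1.10-11	944.75	991.04	1034.31	91.32	idp2395	umc2514	279.67	291.89
SIR6	stem	2	2.02	78.03	90.12	102.14	24.45	umc1265	gpm914a	5.44	9.62
LIR5	leaf	2	2.02	81.21	103.61	124.35	43.81	gpm470	tr1	5.44	12.13
SIR7	stem	2	2.03-04	244.25	250.80	255.67	12.10	bnlg381	ay103944	27.74	32.51
SIR8	stem	2	2.04	312.13	316.24	319.75	8.85	idp267	umc2079	49.81	57.11
KIR3	kernel	2	2.04	311.50	321.20	330.53	19.96	idp8065	mmp89	48.40	61.92
SIR9	stem	2	2.06	376.21	385.08	392.70	17.65	umc1156	gpm738	154.52	186.56
LIR6	leaf	2	2.07-08	456.15	475.69	492.94	36.96	idp6905	tidp3223	198.48	207.19
LIR7	leaf	2	2.07-08	463.12	533.81	602.70	140.45	idp1657	pzb01013	198.48	225.61
SIR10	stem	2	2.08	479.62	494.74	507.53	29.16	idp660	umc116b	204.10	209.85
KIR4	kernel	2	2.08	487.23	516.40	543.06	56.67	w3	tidp6470	204.43	215.01
SIR11	stem	2	2.09	594.45	597.43	598.25	4.73	idp8293	agrx825	222.39	224.60
KIR5	kernel	3	3.01-02	7.39	38.80	68.20	62.24	gpm244	idp4717	1.59	4.87
SIR12	stem	3	3.03	106.82	112.94	116.68	11.26	csu728c	idp1482	8.11	10.08
SIR13	stem	3	3.04	141.57	248.13	251.43	11.42	csu1070	ay110151	67.63	110.72
LIR8	leaf	3	3.04	262.11	273.87	283.48	22.95	csu851b	gpm835e	86.75	119.81
SIR14	stem	3	3.05	323.74	331.40	336.88	14.72	agrr179	umc1307	145.67	152.18
SIR15	stem	3	3.05	368.11	374.89	381.25	14.75	tidp2951	gpm397a	161.20	166.46
KIR6	kernel	3	3.06-08	483.96	543.52	600.64	116.88	gpm513	idp8087	186.39	209.41
LIR9	leaf	3	3.08-09	589.13	658.92	725.53	136.48	umc231	idp8203	206.61	218.85
SIR16	stem	3	3.08-09	616.25	712.10	806.88	191.02	wox9b	phot1	210.58	229.15
LIR10	leaf	4	4.01	64.06	67.59	70.81	7.71	gpm521b	idp483	3.58	5.11
SIR17	stem	4	4.03	171.29	184.69	195.56	25.47	uaz180	gpm760b	17.42	18.62
KIR7	kernel	4	4.03-05	191.52	217.31	242.77	52.59	idp7383	v17	17.93	40.45
LIR11	leaf	4	4.07-08	425.52	436.68	445.75	21.57	pza03275	gpm151c	173.91	181.39
KIR8	kernel	4	4.08-09	567.81	572.67	575.90	8.78	mdr1	rgpr3235b	202.51	216.53
KIR9	kernel	4	4.10	655.48	674.68	693.24	38.70	umc1101	asg41	236.13	239.02
SIR18	stem	5	5.02	151.68	161.10	168.94	17.78	gpm359b	cdo542	8.46	12.29
KIR10	kernel	5	5.02	184.35	204.82	225.05	41.61	idp8235	idp8641	12.29	20.00
SIR19	stem	5	5.02	247.24	253.12	258.34	11.77	idp5851	umc1151	29.90	42.38
SIR20	stem	5	5.04	313.22	325.25	335.41	22.41	umc1591	ay110906	135.81	162.66
LIR12	leaf	5	5.05	397.07	415.03	431.60	35.24	idp4891	gpm922c	174.13	183.57
SIR21	stem	5	5.05	410.63	422.42	432.83	22.40	umc1687	tidp2809	180.15	185.72
SIR22	stem	5	5.05	478.46	483.18	485.86	7.97	phm532	bnlg1237	192.72	195.59
LIR13	leaf	5	5.06-07	500.04	517.88	533.33	33.77	prr1	idp2459	201.26	205.36
SIR23	stem	5	5.07-09	644.31	654.03	662.81	18.68	ay110182	bnlg1885	205.44	217.01
KIR11	kernel	6	6.01	68.88	85.47	101.90	34.02	po1	uaz169	9.41	75.24
SIR24	stem	6	6.01	79.70	91.43	102.47	23.06	mmp13	uaz169	13.92	75.24
LIR14	leaf	6	6.01	79.13	94.08	107.59	28.96	mmp13	mmp10	13.92	70.95
LIR15	leaf	6	6.02-03	148.58	163.80	177.04	28.72	mab26	php20856	93.49	104.54
SIR25	stem	6	6.05	315.95	325.82	335.30	20.09	ufg16	idp8048	144.27	148.36
SIR26	stem	6	6.05	369.46	372.96	375.15	5.96	isu1410i	nfy2	151.11	152.19
KIR12	kernel	6	6.06-07	393.37	425.37	455.99	63.73	idp3915	npi9	153.37	162.29
SIR27	stem	6	6.06-07	422.97	436.49	449.16	27.01	lim151	phi299852	158.22	162.29
SIR28	stem	6	6.07-08	515.76	561.72	606.85	91.61	lhcb7	cdo202	164.90	END
KIR13	kernel	7	7.01-02	120.32	135.87	151.12	31.29	idp1624	gpm804	10.47	17.36
SIR29	stem	7	7.02	177.35	213.57	249.20	72.94	idp8247	tidp3642	40.24	109.48
LIR16	leaf	7	7.02	244.07	256.69	269.16	25.59	tidp8862	tidp2851	104.80	126.88
SIR30	stem	7	7.03	323.33	329.86	335.88	12.81	bnlg434	brd103	132.53	138.76
KIR14	kernel	7	7.03	313.64	331.10	347.85	35.04	idp8017	gpm472	131.98	141.62
LIR17	leaf	7	7.03	322.76	348.96	372.94	50.80	bnlg434	idd7	132.53	146.24
SIR31	stem	7	7.04	486.99	498.92	509.80	23.01	gpm446b	cdo405	163.60	166.90
SIR32	stem	7	7.04-05	533.18	577.14	621.00	88.56	umc245	idp1466	168.36	170.99
LIR18	leaf	8	8.01-02	104.41	133.28	161.35	57.60	gpm850a	pza02454	8.81	20.46
SIR33	stem	8	8.03	260.42	269.56	278.22	18.65	idp8347	pge2	94.99	101.39
LIR19	leaf	8	8.04-05	307.29	321.21	333.39	26.16	gl18	cdo1081b	110.70	125.12
SIR34	stem	8	8.04	327.46	335.19	341.69	15.30	umc160b	rop7	119.11	122.95
KIR15	kernel	8	8.05-06	396.86	401.78	405.17	8.49	umc1287	pza03182	141.95	160.44
LIR20	leaf	8	8.08	521.44	544.70	567.71	47.02	tidp5576	cmu1	170.00	173.11
SIR35	stem	8	8.08-09	551.10	563.84	576.01	25.16	bnlg1056	dupssr14	171.74	175.44
SIR36	stem	9	9.00-01	9.55	23.71	35.81	27.35	rz144a	idp4166	2.78	7.33
SIR37	stem	9	9.02	108.03	118.40	128.32	21.24	umc256a	omt2	12.94	16.32
LIR21	leaf	9	9.02-03	162.34	188.95	214.86	53.02	umc1037	w11	16.97	26.90
KIR16	kernel	9	9.03	222.03	230.63	238.74	17.00	pza03469	idp2479	28.33	90.03
SIR38	stem	9	9.03	233.96	242.92	250.67	17.82	cdo319	tidp5661	26.96	99.16
SIR39	stem	9	9.04	294.24	297.95	300.21	5.99	csu263a	gpm622a	113.01	119.47
LIR22	leaf	9	9.04-05	297.23	310.61	323.49	26.88	umc2398	lim458	114.05	133.59
LIR23	leaf	9	9.05-06	378.40	407.06	435.69	57.64	idp708	rps22a	134.38	142.49
KIR17	kernel	9	9.06	498.36	500.66	501.94	4.21	idp4802	gpm499	145.30	146.70
SIR40	stem	10	10.03	174.87	181.54	187.40	13.01	idp8241	cx1	42.25	64.26
LIR24	leaf	10	10.03	202.33	211.79	219.67	17.75	ufg59	umc1938	66.71	83.67
SIR41	stem	10	10.03-04	233.64	240.50	246.17	13.06	idp1446	idp4425	87.12	97.76
KIR18	kernel	10	10.04	260.14	267.21	273.63	13.57	odo1	bnlg2127	109.79	117.83
SIR42	stem	10	10.05	314.10	326.44	337.22	23.31	idp7650	gpm256	127.51	132.73
KIR19	kernel	10	10.07	435.49	464.22	491.38	56.40	idp2467	rz17a	144.24	149.07
KIR20	kernel	10	10.07	489.93	566.62	577.61	153.19	ren3	gpm835a	146.29	149.79
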