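locus_id	gene_name	product	shock_ratio	nfix_fold	nifa_flag	rpon_flag
PST1302	.	glutaredoxin-related protein	0.06	16.83	.	.
PST1303	.	thiosulfate sulfurtransferase glpE	0.03	53.99	.	.
PST1304	nifQ	nitrogen fixation protein NifQ	0.03	46.56	.	.
PST1305	.	arsenate reductase related protein	0.03	38.67	.	.
PST1306	nifB	FeMo cofactor biosynthesis protein NifB	0.06	21.46	Yes	Yes
PST1307	.	conserved hypothetical protein	0.57	1.87	No	Yes
PST1308	.	transcriptional regulator, LysR family	0.43	2.22	No	No
PST1309	.	conserved hypothetical protein	0.84	1.12	No	No
PST1310	.	transcriptional regulator, AraC family	1.03	1.02	No	No
PST1311	.	fosmidomycin resistance protein	0.81	1.34	No	Yes
PST1312	tpmA	thiopurine s-methyltransferase	0.34	2.65	No	Yes
PST1313	nifA	positive regulatory protein	0.15	6.95	.	.
PST1314	nifL	negative regulatory protein	0.12	7.68	Yes	Yes
PST1315	rnfA	electron transport complex, A subunit	0.37	2.66	Yes	Yes
PST1316	rnfB	electron transport complex, B subunit	0.10	9.94	.	.
PST1317	rnfC	electron transport complex, C subunit	0.49	2.22	.	.
PST1318	rnfD	electron transport complex, D subunit	0.13	7.67	.	.
PST1319	rnfG	electron transport complex, G subunit	0.16	7.47	.	.
PST1320	rnfE	electron transport complex, E subunit	0.15	8.80	.	.
PST1321	rnfH	electron transport complex, H subunit	0.21	17.55	.	.
PST1322	nifY2	iron-molybdenum cofactor biosynthesis protein	0.10	21.74	.	.
PST1323	.	nitrogen fixation-related protein	0.18	13.73	.	.
PST1324	.	conserved hypothetical protein	0.15	25.99	.	.
PST1325	.	conserved hypothetical protein	0.15	9.68	Yes	Yes
PST1326	nifH	Fe protein	0.32	94.05	Yes	Yes
PST1327	nifD	MoFe protein, alpha subunit	0.56	54.16	.	.
PST1328	nifK	MoFe protein, beta subunit	0.62	38.22	.	.
PST1329	nifT	nitrogen fixation protein	1.70	7.82	.	.
PST1330	nifY	iron-molybdenum cofactor biosynthesis protein	0.33	8.51	.	.
PST1331	.	conserved hypothetical protein	0.41	12.55	.	.
PST1332	.	leucine-rich repeat domain protein	0.57	3.27	No	Yes
PST1333	nifE	iron-molybdenum cofactor biosynthesis protein	0.05	35.82	Yes	Yes
PST1334	nifN	iron-molybdenum cofactor biosynthesis protein	0.07	13.32	.	.
PST1335	nifX	iron-molybdenum cofactor biosynthesis protein	0.10	37.97	.	.
PST1336	.	protein of unknown function DUF269	0.29	5.06	.	.
PST1337	.	protein of unknown function DUF683	0.05	63.84	.	.
PST1338	.	ferredoxin, 4Fe-4S	0.08	31.07	Yes	Yes
PST1339	.	ferredoxin, 2Fe-2S	0.76	2.94	.	.
PST1340	.	conserved hypothetical protein	0.82	1.28	.	.
PST1341	.	conserved hypothetical protein	0.85	1.28	.	.
PST1342	.	conserved hypothetical protein	0.43	3.69	.	.
PST1343	.	conserved hypothetical protein	0.70	2.56	.	.
PST1344	.	conserved hypothetical protein	0.21	7.16	Yes	Yes
PST1345	modC	molybdenum transport protein ModC	0.79	1.59	.	.
PST1346	modB	molybdate ABC transporter	0.48	2.05	.	.
PST1347	modA	molybdenum ABC transporter	0.20	4.12	.	.
PST1348	.	putative molybdenum-binding protein	0.22	3.88	Yes	Yes
PST1349	hesB	Fe-S cluster assembly protein	0.07	20.92	Yes	Yes
PST1350	nifU	Fe-S cluster assembly protein NifU	0.11	10.77	.	.
PST1351	nifS	nitrogenase metalloclusters biosynthesis protein	0.11	16.21	.	.
PST1352	nifV	homocitrate synthase	0.05	24.55	.	.
PST1353	cysE	serine acetyltransferase (cysE-like)	0.05	32.98	.	.
PST1354	.	conserved hypothetical protein	0.10	11.11	.	.
PST1355	nifW	nitrogenase stabilizing/protective protein	0.16	26.04	.	.
PST1356	nifZ	Fe-S cofactor synthesis protein	0.17	18.17	.	.
PST1357	nifM	putative peptidyl-prolyl cis/trans isomerase	0.19	18.78	.	.
PST1358	.	ATP-dependent Clp protease	0.56	8.42	.	.
PST1359	nifF	flavodoxin for electron transfer	0.86	14.91	Yes	Yes
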