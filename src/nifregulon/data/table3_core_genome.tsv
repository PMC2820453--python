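gene_id	gene_name	product
PST0200	.	4-hydroxyphenylpyruvate dioxygenase
PST0349	ntrC	nitrogen regulation protein NtrC
PST0350	ntrB	nitrogen regulation protein NtrB
PST0353	glnA	glutamine synthetase
PST0502	glnK	nitrogen regulatory protein P-II
PST0503	amtB1	ammonium transporter
PST0722	prkA	serine protein kinase PrkA
PST0754	.	membrane protein
PST0813	.	major facilitator family transporter
PST1140	.	conserved hypothetical protein
PST1301	cobs	cobalamin (5'-phosphate) synthase
PST1346	modB	molybdate ABC transporter, permease protein
PST1347	modA	molybdenum ABC transporter, periplasmic binding protein
PST1563	adhC	alcohol dehydrogenase class III
PST2137	glgA	glycogen synthase
PST2154	.	alpha-amylase family protein
PST2381	.	conserved hypothetical protein
PST2748	.	OmpA family protein
PST2982	braC	branched-chain amino acid transport protein BraC
PST3253	.	membrane protein, putative
PST3727	urea	urease, gamma subunit
PST3736	ureE	urease accessory protein UreE
PST3780	rodA	rod-shape-determining protein RodA
PST3795	.	ribosome-associated GTPase
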