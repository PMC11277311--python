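chrom	pos	ref	alt	gene	hgvs_c	hgvs_p	seq_ontology	score	oncogenicity	cosmic_id	cosmic_count
17	7578205	C	T	TP53	NM_000546.6:c.644G>A	p.Ser215Asn	missense	9	O	COSM44093	29
17	7578262	C	G	TP53	NM_000546.6:c.587G>C	p.Arg196Pro	missense	9	O	COSM43814	36
17	7577539	G	A	TP53	NM_000546.6:c.742C>T	p.Arg248Trp	missense	9	O	COSM10656	1044
17	7578291	T	A	TP53	NM_000546.6:c.560-2A>T	p.?	splice_variant	4	LO	COSM45026	15
17	7578550	G	T	TP53	NM_000546.6:c.380C>A	p.Ser127Tyr	missense	8	O	COSM43970	37
21	36171607	G	A	RUNX1	NM_001754.5:c.958C>T	p.Arg320Ter	frameshift	7	O	COSM41699	21
1	27087503	C	T	ARID1A	NM_006015.6:c.2077C>T	p.Arg693Ter	frameshift	6	O	COSM184236	37
5	112164616	C	T	APC	NM_000038.6:c.1690C>T	p.Arg564Ter	frameshift	9	O	COSM18848	82
17	7577548	C	T	TP53	NM_000546.6:c.733G>A	p.Gly245Ser	missense	9	O	COSM6932	670
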