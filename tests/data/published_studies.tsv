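study_id	focal_taxon	scope	markers	n_species	n_genera
s01	Galkinia	genus	12S;COI	8	1
s02	Pollicipes	genus	COI;H3;16S	4	1
s03	Chthamalus	genus	16S;NKA;EF1a	18	2
s04	Conopea	genus	COI;H3	4	1
s05	Heterosaccus	genus	16S;18S	4	1
s06	Polysacus	genus	18S;COI	7	1
s07	Bryozobiinae	subfamily	morphology	5	5
s08	Pyrgomatinae	subfamily	12S	5	2
s09	Pyrgomatidae	family	COI;16S;12S;18S;H3;morphology	22	15
s10	Pyrgomatidae	family	12S;16S;EF1a;H3;RPII	26	11
s11	Pyrgomatidae	family	12S;16S;18S	27	20
s12	Tetraclitidae	family	12S;16S;18S;COI;EF1;H3;RPII	30	8
s13	Coronuloidea	superfamily	12S;16S;18S;28S;H3	27	19
s14	Balanomorpha	suborder	12S;16S;18S;28S;COI	124	65
s15	Lithoglyptida	order	16S;COI	5	5
s16	Akentrogonida	order	18S;28S	15	11
s17	Scalpelliformes	order	18S;28S;COI	10	6
s18	Acrothoracica	superorder	16S;18S;COI;H3	22	8
s19	Rhizocephala	superorder	16S;18S;28S	27	16
s20	Rhizocephala	superorder	18S	22	16
s21	Thoracica	superorder	12S;18S;COI;H3	78	36
s22	Thoracica	superorder	16S;18S;28S	98	59
s23	Thoracica	superorder	28S;COI;H3	100	52
s24	Thoracica	superorder	18S;28S;H3	76	43
s25	Thoracica	superorder	18S	48	27
s26	Thecostraca	subclass	18S;28S;H3;morphology	79	66
s27	Thecostraca	subclass	18S	8	8
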