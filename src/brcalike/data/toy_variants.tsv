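variant_id	patient_id	gene	variant_class	severity	sift	polyphen	population_frequency	classification
V01	P01	TP53	missense	HIGH	deleterious	damaging	0.001	unclassified
V02	P02	TP53	synonymous	LOW			0.0001	unclassified
V03	P03	PTEN	missense	MODERATE	deleterious	damaging		unclassified
V04	P04	PTEN	missense	LOW	deleterious	damaging	0.0001	unclassified
V05	P05	ATM	missense	MODERATE	tolerated	benign	0.0001	unclassified
V06	P06	ATM	missense	MODERATE	tolerated	damaging	0.0001	unclassified
V07	P07	CHEK2	missense	MODERATE	deleterious	benign	0.0001	unclassified
V08	P08	CHEK2	missense	HIGH	deleterious	damaging	0.02	unclassified
V09	P09	BRCA1	missense	MODERATE	deleterious	damaging	0.0001	pathogenic
V10	P10	BRCA1	missense	MODERATE	deleterious	damaging	0.0001	VUS
V11	P11	BRCA1	missense	MODERATE	deleterious	damaging	0.0001	likely-benign
V12	P12	BRCA2	missense	MODERATE	deleterious	damaging	0.0001	benign
V13	P13	BRCA2	nonsense	HIGH			0.0001	likely-pathogenic
V14	P14	BRCA2	synonymous	LOW			0.0001	VUS
V15	P15	BRCA1	missense	MODERATE	tolerated	benign	0.0001	pathogenic
V16	P16	NBN	frameshift	HIGH				unclassified
V17	P17	NBN	other	MODIFIER			0.0001	unclassified
V18	P18	PALB2	splice	HIGH			0.05	unclassified
V19	P19	PALB2	missense	MODERATE	deleterious	damaging	0.01	unclassified
V20	P20	BARD1	missense	MODERATE				unclassified
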