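# Default registry of well-characterised human imprinted DMRs (GRCh38).
# Coordinates are approximate region anchors for QC scoring; supply your
# own BED6+2 (name, score, strand, germline_origin, notes) for exact work.
chr11	1999000	2003000	H19_ICR1	0	.	paternal	H19/IGF2 imprinting control region
chr11	2698000	2701000	KCNQ1OT1_ICR2	0	.	maternal	KvDMR1
chr14	100810000	100813000	MEG3_IG_DMR	0	.	paternal	DLK1/MEG3 intergenic DMR
chr15	23565000	23568000	MKRN3	0	.	maternal	Prader-Willi region
chr15	24954000	24958000	SNRPN	0	.	maternal	PWS imprinting centre
chr19	56837000	56841000	PEG3	0	.	maternal	PEG3/ZIM2 promoter DMR
chr6	144006000	144009000	PLAGL1	0	.	maternal	ZAC1 DMR
chr7	50781000	50785000	GRB10	0	.	maternal	GRB10 CpG island
chr7	130490000	130494000	MEST	0	.	maternal	MEST/PEG1 promoter
chr20	58850000	58855000	GNAS_XL	0	.	maternal	GNAS XLas DMR
chr2	206249000	206252000	ZDBF2	0	.	paternal	GPR1/ZDBF2 DMR
chr13	48318000	48321000	RB1_CpG85	0	.	maternal	RB1 intragenic DMR
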