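patient_id	peptide_mt	db_id	score	bitscore	evalue
P0001	MAACCLLEK	VIRDB_00001	26	14.623421253895188	0.012480216437383248
P0003	SIINFEKV	VIRDB_00002	35	18.09021743715137	0.0010033673266226558
P0004	GILGFVFTV	VIRDB_00003	42	20.78661446857284	0.00017414703733316774
P0005	GILGFVFSL	VIRDB_00003	41	20.401414892655488	0.00022744307436577116
P0006	KLVVVGADV	VIRDB_00005	41	20.401414892655488	0.00022744307436577116
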