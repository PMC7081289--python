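patient_id	peptide_mt	peptide_wt	hla_allele	ic50_mt	ic50_wt
P0001	MAACCLLEK	MAACCILEK	HLA-A*02:01	100.0	400.0
P0002	YLEPGPVTA	YLEPGPVSA	HLA-A*02:01	9000.0	9500.0
P0003	SIINFEKV	SIANFEKV	HLA-B*07:02	50.0	500.0
P0003	KLNDLSTRK	KLNDLSTRQ	HLA-A*01:01	300.0	600.0
P0004	KMNDLSTRA	KLNDLSTRA	HLA-A*01:01	150.0	450.0
P0004	GILGFVFTV	GILGYVFTV	HLA-A*02:01	80.0	320.0
P0005	GILGFVFSL	GILGYVFSL	HLA-A*02:01	40.0	200.0
P0005	AVDPIHGEF	AVDPIHGEY	HLA-B*08:01	2000.0	2400.0
P0006	KLVVVGADV	KLVVVGAGV	HLA-A*02:01	120.0	240.0
P0006	RLMNPTTAK	RLMNPTSAK	HLA-A*01:01	450.0	900.0
P0006	FLPSDFFPS	FLPSDYFPS	HLA-B*07:02	600.0	700.0
P0006	HMTEVVRHC	HMTEVVRRC	HLA-C*07:01	350.0	550.0
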