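patient_id	immunogenicity	tumor_fitness	argmax_peptide	n_epitopes	flagged
P0001	2.0	0.5	MAACCLLEK	1	0
P0002	0.0			0	1
P0003	8.333333333333332	0.12000000000000002	SIINFEKV	2	0
P0004	2.844444444444444	0.35156250000000006	GILGFVFTV	2	0
P0005	0.4166666666666666	2.4000000000000004	GILGFVFSL	1	0
P0006	0.5333333333333332	1.8750000000000004	KLVVVGADV	3	0
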