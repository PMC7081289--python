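patient_id	time	event	stage	tmb	cyt	til_burden	til_clonality	immunogenicity
P0001	900.0	1	2	120.0	8.5	3.1	0.42	
P0002	1500.0	0	1	45.0	2.1	0.8	0.21	
P0003	400.0	1	3	310.0	12.0	5.6	0.55	
P0004	2200.0	0	2	95.0	6.3	2.2	0.38	
P0005	750.0	1	4	200.0	1.2	0.5	0.15	
P0006	1100.0	1	1	150.0	9.9	4.4	0.47	
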