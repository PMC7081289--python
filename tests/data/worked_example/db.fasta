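>VIRDB_00001
AACC
>VIRDB_00002
SIINFEKL
>VIRDB_00003
GILGFVFTL
>VIRDB_00004
WWWWW
>VIRDB_00005
KLVVVGADV
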