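category	level	count
site	colon	169
site	rectal	48
sex	male	118
sex	female	99
race	non_hispanic_white	161
race	hispanic	14
race	non_hispanic_black	8
race	unknown	34
stage	1	58
stage	2	61
stage	3	72
stage	4	23
phenotype	MSS	187
phenotype	MSI	29
vital	dead	92
vital	alive	124
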