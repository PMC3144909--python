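gene_symbol	species	atg	g_plus4	r_minus3	strength
COMT	panda	y			W
COMT	human	y		y	A
MC4R	panda	y		y	A
MC4R	human	y	y	y	S
OPRD1	panda	y	y		A
OPRD1	human	y	y	y	S
GRM7	panda	y		y	A
GRM7	human	y	y	y	S
ADRA1D	panda	y	y	y	S
ADRA1D	human	y		y	A
GRIA3	panda	y	y	y	S
GRIA3	human	y	y		A
HTR3E	panda	y	y	y	S
HTR3E	human	y			W
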