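gene_symbol	structure_id	coverage_count	coverage_total	coverage_pct	consensus_count	consensus_total	consensus_pct
COMT	3BWM	214	271	78.97	206	271	76.01
LEP	1AX8	145	167	86.83	136	167	81.44
ALDH2	1O05	500	517	96.71	479	517	92.65
MAOA	2BXR	527	527	100.00	454	527	86.15
PNMT	1YZ3	282	282	100.00	247	282	87.59
MAOB	1GOS	520	520	100.00	475	520	91.35
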