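# Versioned nearest-neighbor duplex parameters (v1).
# key = top-strand dimer 5'->3' / the bases paired to it, in column order.
# Watson-Crick stacks: Turner-style dG37 (kcal/mol); any step containing
# a G:U wobble uses a uniform simplified value.
param	key	value
init	-	4.09
terminal_au	-	0.45
mismatch	-	0.50
stack	AA/UU	-0.93
stack	AU/UA	-1.10
stack	AG/UC	-2.08
stack	AC/UG	-2.24
stack	AG/UU	-1.30
stack	AU/UG	-1.30
stack	UA/AU	-1.33
stack	UU/AA	-0.93
stack	UG/AC	-2.11
stack	UC/AG	-2.35
stack	UG/AU	-1.30
stack	UU/AG	-1.30
stack	GA/CU	-2.35
stack	GU/CA	-2.24
stack	GG/CC	-3.26
stack	GC/CG	-3.42
stack	GG/CU	-1.30
stack	GU/CG	-1.30
stack	CA/GU	-2.11
stack	CU/GA	-2.08
stack	CG/GC	-2.36
stack	CC/GG	-3.26
stack	CG/GU	-1.30
stack	CU/GG	-1.30
stack	GA/UU	-1.30
stack	GU/UA	-1.30
stack	GG/UC	-1.30
stack	GC/UG	-1.30
stack	GG/UU	-1.30
stack	GU/UG	-1.30
stack	UA/GU	-1.30
stack	UU/GA	-1.30
stack	UG/GC	-1.30
stack	UC/GG	-1.30
stack	UG/GU	-1.30
stack	UU/GG	-1.30
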