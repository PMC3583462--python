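line	class	B224C4P2	Ca_Sb07g023840	RGR1963	Ca_Sb07g023910	Ca_Sb07g024020	Ca_Sb07g023810	Ca_Sb07g023630	Ca_Sb07g023520	Ca_Sb07g023440	Ca_Sb07g023430	PSMP344	PSMP305
ICMP_451	tall	b	b	b	b	ND	b	b	b	b	b	b	b
P1449-2	tall	b	b	b	b	b	c	c	b	b	b	b	b
Tift_red	tall	b	b	b	a	b	b	b	b	c	a	a	a
Tift_23DB	dwarf	a	a	a	a	ND	a	a	a	a	a	a	a
81B	dwarf	a	a	a	a	ND	a	a	a	a	a	b	b
PT_732B	dwarf	a	a	a	a	a	a	a	a	a	a	a	a
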