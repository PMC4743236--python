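root	MPP
MPP	CMP
MPP	CLP
CMP	MEP
CMP	GMP
MEP	EC
MEP	MK
GMP	M
GMP	N-E-B
CLP	B_PROG
CLP	T-NK_PROG
B_PROG	B
T-NK_PROG	T
T-NK_PROG	NK
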