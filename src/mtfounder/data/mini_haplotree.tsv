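# synthetic mini haplogroup tree fixture: real phylotree-style
# topology over familiar haplogroup names, synthetic defining
# variants except where published branch variants are reused
#node	parent	variants
H2a2a1	-	
M	H2a2a1	T14711A C9454A
M5	M	T6853A
M5a	M5	T11741A C12235A
M5a1	M5a	G10133A
M5a1b	M5a1	A3171G G10758T
M5a1b1	M5a1b	A9630T
M5a1b1a	M5a1b1	G13746C
M5a1b1a1	M5a1b1a	C10625G A8069T
M18	M	C10897T T8525G
M1	M	T15976G
M1a	M1	T15132G
U	H2a2a1	T14438G
U3	U	G6565C T5843G
U3b	U3	A5554T
U3b1	U3b	G3717C A9046T
U3b1c	U3b1	A2833G T7759C T8895C C11119T T12783C T15262C
U6	U	G3562A
K	U	G13927A T10596G
K1	K	A13810G
K1a	K1	T12330G
K1a4	K1a	A10511T
J	H2a2a1	G11442T G5806T
J1	J	C12958G
J1b	J1	A1616G
J1b3	J1b	A5524C
J1b3a	J1b3	G9212A
J1c	J1	T1024C
J1c1	J1c	A10955C
J1c1b	J1c1	G9590C
J2	J	G9043C
J2b	J2	C2705A
J2b1	J2b	A15867G
J2b1c	J2b1	C9657A
H	H2a2a1	T13714C
H1	H	A718T
H1j	H1	G806C
H1j1	H1j	G3673T
H3	H	A7241G
H3g	H3	T5219C
H3g1	H3g	A623C
H7	H	G8962T
H7a	H7	T7100C
H7a1	H7a	C16261T
H88	H	G13917C
H88a	H88	G9181T
T	H2a2a1	C14728A G16404C
T2	T	T8555A
V	H2a2a1	C15771G
W	H2a2a1	T6167C
X	H2a2a1	G10142A
T2b	T2	@14728 T6490A
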