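source	target
P1	M1
P2	M2
M1	E1
M1	E2
M2	E3
E1	R1
E2	R2
E3	R3
E3	R4
R1	C01
R1	C02
R2	C03
R2	C04
R3	C05
R3	C06
R4	C07
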