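P1	Methylxanthine degradation (toy)	C01	C02	C03	C04
P2	Glycerophospholipid turnover (toy)	C05	C06	C07
P3	Amino acid interconversion (toy)	C07	C08	C09	C10
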