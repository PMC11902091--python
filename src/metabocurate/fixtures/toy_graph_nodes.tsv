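node_id	node_type
P1	pathway
P2	pathway
M1	module
M2	module
E1	enzyme
E2	enzyme
E3	enzyme
R1	reaction
R2	reaction
R3	reaction
R4	reaction
C01	compound
C02	compound
C03	compound
C04	compound
C05	compound
C06	compound
C07	compound
C08	compound
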