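# Ring definitions for ligand stacking metrics, keyed by residue name and
# ring label; atom names are comma-separated.
# LIG is the package's mock tri-ring ligand (exact). The EGC entry uses
# synthetic catechin-style numbering as a fallback when no chemical-component
# dictionary is available offline; override with your own file for deposited
# models whose component uses different atom names.
residue	ring	atoms
LIG	RA	A1,A2,A3,A4,A5,A6
LIG	RC	C1,C2,C3,C4,C5,C6
LIG	RD	D1,D2,D3,D4,D5,D6
EGC	A	C5,C6,C7,C8,C9,C10
EGC	C	O1,C2,C3,C4,C9,C10
EGC	B	C1',C2',C3',C4',C5',C6'
EGC	D	C1'',C2'',C3'',C4'',C5'',C6''
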