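# Per-residue ordering penalty, kcal/mol, applied once per scored residue.
# Side-chain conformational entropy scale (T*dS near 298 K): the free-energy
# cost of immobilizing the side chain on going from a disordered chain to the
# ordered fibril. Gly/Ala/Pro carry no rotatable side-chain penalty here.
# Stand-in scale; editable, and switchable off in stability_map().
residue	penalty
ALA	0.00
ARG	2.03
ASN	1.57
ASP	1.25
CYS	1.22
GLN	2.11
GLU	1.81
GLY	0.00
HIS	0.96
ILE	0.89
LEU	0.78
LYS	1.94
MET	1.61
PHE	0.58
PRO	0.00
SER	1.71
THR	1.63
TRP	0.97
TYR	0.99
VAL	0.51
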