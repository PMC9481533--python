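# Element-keyed van der Waals radii, Angstrom (Bondi-type set).
# One declared set so every area-dependent result is reproducible.
element	radius
H	1.20
C	1.70
N	1.55
O	1.52
F	1.47
P	1.80
S	1.80
CL	1.75
BR	1.85
I	1.98
SE	1.90
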