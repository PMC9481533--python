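# Atomic solvation parameters, cal/mol/A^2, keyed by heavy-atom class.
# Classic atom-class transfer-energy coefficients (carbon, neutral N/O,
# charged carboxylate O-, charged N+, sulfur). Editable; the table id is
# stamped into every energy-map output.
class	asp
C	16.0
N/O	-6.0
O-	-24.0
N+	-50.0
S	21.0
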