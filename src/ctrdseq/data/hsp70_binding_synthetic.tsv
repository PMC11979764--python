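# Synthetic default HSP70/HSC70 binding-propensity table.
# Encodes the qualitative substrate preferences of the DnaK/HSP70 family:
# aliphatic and aromatic residues (core binders) score high, basic
# residues (favoured in the flanks of binding sites) mildly positive,
# acidic residues and proline strongly negative. Replace with a
# user-supplied TSV (residue<TAB>score) to use a published energy table.
residue	score
A	0.30
R	0.40
N	-0.10
D	-0.90
C	0.20
Q	-0.10
E	-1.00
G	0.00
H	0.15
I	0.90
L	1.00
K	0.30
M	0.70
F	0.85
P	-0.40
S	0.05
T	0.10
W	0.60
Y	0.45
V	0.80
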