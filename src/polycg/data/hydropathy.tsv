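# Relative hydrophobic strength eps_i per amino acid, dimensionless, in (0, 1).
# This table is an *input* to the force field, not a derived quantity: values
# here are a min-max normalisation of the Monera et al. (1995) pH-7
# hydrophobicity scale onto [0.01, 0.99], with the charged residues (D, E, K,
# R) raised by +0.05 to reflect their slightly strengthened short-range
# attraction in the residue-scale force-field lineage this package follows.
# Replace this file (or pass a custom table) to use a different calibration.
# residue	eps_i
A	0.617
R	0.319
N	0.181
D	0.060
C	0.668
Q	0.295
E	0.212
G	0.358
H	0.408
I	0.984
L	0.971
K	0.262
M	0.826
F	0.990
P	0.067
S	0.326
T	0.440
V	0.838
W	0.971
Y	0.756
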