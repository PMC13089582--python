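# Synthetic per-residue compressibility magnitude scale K0 (m^3 mol^-1 Pa^-1 x 1e-15).
# SYNTHETIC reconstruction: not a transcription of any published table. The pairwise
# differences reported for rhodopsin substitution screens (S->A ~ -4.29, L->P ~ -8.39,
# I->V ~ -1.14, K->H -1.50, F->L -2.75, T->S -1.18) are encoded exactly; all other
# values are plausible magnitudes chosen once. Analyses that must match a published
# scale should inject that scale via AminoAcidPropertyScale.from_file.
aa	K0
A	12.50
R	23.70
N	15.70
D	14.60
C	15.20
Q	18.20
E	16.90
G	10.80
H	20.90
I	19.54
L	21.30
K	22.40
M	22.10
F	24.05
P	12.91
S	16.79
T	17.97
W	26.50
Y	24.80
V	18.40
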