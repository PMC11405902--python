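# Monoisotopic residue masses (Da) for the 20 canonical amino acids,
# IUPAC/CODATA values. A residue mass is the amino-acid mass minus water;
# peptide mass = sum(residues) + water.
# columns: residue	mass_da
G	57.021464
A	71.037114
S	87.032028
P	97.052764
V	99.068414
T	101.047678
C	103.009185
L	113.084064
I	113.084064
N	114.042927
D	115.026943
Q	128.058578
K	128.094963
E	129.042593
M	131.040485
H	137.058912
F	147.068414
R	156.101111
Y	163.063329
W	186.079313
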