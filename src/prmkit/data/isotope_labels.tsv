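# Stable-isotope-label compositions for SIL reference peptides: the six
# residues available as fully 13C/15N-substituted heavy amino acids.
# columns: residue	n_13c	n_15n
V	5	1
L	6	1
I	6	1
A	3	1
F	9	1
K	6	2
R	6	4
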