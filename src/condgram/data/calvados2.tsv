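# condgram bead parameter table, version 1 (CALVADOS 2 single-bead force field)
# sigma: bead diameter from van der Waals radii, nm
# lam: CALVADOS 2 hydrophobicity ("stickiness"), dimensionless
# charge: elementary charges at neutral pH
# mass: standard average residue mass (monomer minus water), Da; U is the UMP residue
# species: protein | rna
name	sigma	lam	charge	mass	species
A	0.504	0.2743297969040348	0.0	71.0788	protein
R	0.656	0.7307624767517166	1.0	156.1875	protein
N	0.568	0.4255883895916301	0.0	114.1038	protein
D	0.558	0.0416040480605567	-1.0	115.0886	protein
C	0.548	0.5615435099141777	0.0	103.1388	protein
Q	0.602	0.3934318551056041	0.0	128.1307	protein
E	0.592	0.0006935460962935	-1.0	129.1155	protein
G	0.450	0.7058843733666401	0.0	57.0519	protein
H	0.608	0.4663667290557992	0.0	137.1411	protein
I	0.618	0.5423623610671892	0.0	113.1594	protein
L	0.618	0.6440005007782226	0.0	113.1594	protein
K	0.636	0.1790211738990582	1.0	128.1741	protein
M	0.618	0.5308481134337497	0.0	131.1926	protein
F	0.636	0.8672358982062975	0.0	147.1766	protein
P	0.556	0.3593126576364644	0.0	97.1167	protein
S	0.518	0.4625416811611541	0.0	87.0782	protein
T	0.562	0.3713162976273964	0.0	101.1051	protein
W	0.678	0.9893764740371644	0.0	186.2132	protein
Y	0.646	0.9774611449343455	0.0	163.1760	protein
V	0.586	0.2083769608174481	0.0	99.1326	protein
U	0.817	-0.027	-1.0	306.1700	rna
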