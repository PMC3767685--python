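group	fluorescent	radio	mrna
Unknown function	46	26	1496
Chromosome replication	1	1	8
Chaperones	16	13	14
Protection responses	8	4	54
Transport/binding proteins	30	21	435
Adaptation	4	1	31
Cell division	2	2	14
Differentiation/sporulation	1	1	10
Macromolecule degradation	18	6	152
Macromolecule synthesis, modification	22	15	209
Amino acid biosynthesis	1	0	99
Biosynthesis of cofactors, carriers	6	6	88
Central intermediary metabolism	3	3	78
Degradation of small molecules	4	3	142
Energy metabolism, carbon	25	17	152
Fatty acid biosynthesis	1	0	45
Nucleotide biosynthesis	0	0	28
Secondary metabolism	0	0	163
Periplasmic/exported/lipoproteins	32	13	944
Ribosome constituents	5	4	60
Laterally acquired elements	0	0	76
Regulation/Two component system	3	3	121
Regulation/RNApolymerase core enzyme binding	4	4	68
Regulation/Defined families	3	2	325
Regulation/Protein kinases	0	0	35
Regulation/Others	5	4	175
Not classified (including putative assignments)	11	2	363
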