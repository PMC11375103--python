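name	lineage	p_variant	q_count	source_accession	edits
C1	C	.	1	NC_001566	.
C2	C	.	1	NC_061380.1	sub:100:T>G;sub:460:G>C
C2c	C	.	1	MN_250878.1	sub:100:T>G;sub:460:G>C;del:500:C
A1a	A	P0	1	KX463739	.
A1e	A	P0	1	MW677198	sub:300:C>G
A4	A	P0	2	EF033650	sub:350:T>G
A26	A	P	0	EF033651	ins:134:CGCGTTTAACGCCCTTGGCTGTAGAGTTCCCTGCAGCTCCTTTCGAAGCATAGACAAGTGAGTTTAACTTAAACCAGGCGATTGGCCCTACCTGACATTCGCCCAGCTGCCCCGCGTTCAACGACAGGCA
A65	A	P0	2	MW677213	sub:360:T>G;sub:600:T>G
A2w	A	P0	2	OY748522	sub:158:C>A;sub:216:C>T;sub:412:C>A;sub:219:A>T;sub:410:A>T
A6a	A	P0	2	OY748523	sub:158:C>A;sub:216:C>T;sub:412:C>A
M3	M	P	2	FJ743636.1	sub:200:A>G
M3a	M	P	2	KX463884	sub:200:A>G;sub:210:A>G
M4	M	P	1	EF033656	sub:250:G>C
M79	M	P0	2	KX463882	sub:250:C>G;sub:620:C>G
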