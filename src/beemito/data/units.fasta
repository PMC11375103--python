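>P0
CGCTGGTCTTACAGGGTCCACGCACCTCCATCAGAAAAGCCTCTCAGGAGTGACCAACAT
AAGGTGCG
>P
CGCTGGTCTTACAGGGTCCACGCACCTCCTCAGGAGTGACCAACATAAGGTGCG
>P1
CGCTGGTCTTACAGGGTCCACGCAAGGAGTGACCAACATAAGGTGCG
>P2
CGCTGGTCTTACAGGGTCCACGCACCTCCATCCCTCTCAGGAGTGACCAACATAAGGTGC
G
>Q
CGCGTTTAACGCCCTTGGCTGTAGAGTTCCCTGCAGCTCCTTTCGAAGCATAGACAAGTG
AGTTTAACTTAAACCAGGCGATTGGCCCTACCTGACATTCGCCCAGCTGCCCCGCGTTCA
ACGACAGGCATCAGCCCGCGGCTTCCAACCACTACTTATCACACAATCTGTCTATATGAA
GATGAAAATGGCCGCG
>ANCHOR5
CGCATACCTATCTCAATAAGCAATCGTTCTATCCTGAGAAAGCTTTTAAACCACTGATGA
TGCAAAGCTGGATGACTGCG
>ANCHOR3
CGCCGTCCTGTGTCGTACAACGGCATAATGCTCGAGATTTTCTTGTCCTGGATATCGGCT
AGTCCCTTTTGTCACCCCCCCTTAAGTTTACCACCGAAGGTGCAACCGCGTATTACAGAT
CGTCTAATAGCTCACATGCAGACTATACCATACTGGGCCCGGACGGCGCTGCAACGTCTC
GACGGGGGTGGCTGGTGCTCAGTTTACCAGTCACGAAATATGGCTTGTATCCTAAGCATC
ATGCCTAGTGTGGGGGAAAGTACTGTCGCCCATAGCTCTTTCTTTAGCG
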