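>env_reference_cds
ATGCACCAGTACAAGAAGTGGATGGGCAGCATCCCTGAACATTATATGCACGTCCTGAAGTGGGTGTCGG
GAGATCTCGCCCTCGTTTTGTTTAGTATGTTACAGCGAGGTGCGGGTCTATGCGCTAAGCAAATGACGCT
CCCTTTCGACATAAGACTTCGATGGATCATGAAAATGACTATCCGTGCGTTATATGTGTCAGCCGTTATA
CGAATTATGAACATGCACTGTCACAAGCAGTTCCTACACCTGATGCTGAATATCTGTGATGACACTTACG
GTCCCCATACAAATAATTCCGATGGGGGCGGGTGGAAAGACTATACGCGGTTCAAGCATACTCCAAGTCA
CCAGGTCCGGGAGCCAGAGATGTACCACTGTCAAAATTGTTATCACCTGTTCGTGCGGTTCGAAATTAGA
TTCAACCACCCCAGCCAGATAACCAAGTCTATTGGAATGGGATGCGCAACACATTGCATGAGGTATAATC
ACTATGGGGCGGGCCATCACTACTCAAAAGAACACTGCCATGACTGTGCGGTGTATACAGACTTTTGCTG
GATATGTGCCGAATGCGAAGCGGGCGCCTTCCAGGCGTTGATGTGGGAGGATTGTCAAATAGCCGAACAT
GTAAATCGTGACAAGTTAGATTCAATTAGCATATGGACCGCGTGCATTCAAACACAATTTAATTATATGC
AGACGTGTGTATGCTGTCAAATAATGGGTCTAATTATCTCGTGTGGAATTGAAATATGGGAGGCAAAGCC
TATCTTTATATGGCGTGAATACATGGCGAATTGGCTATGGTGGGACGGACAAACTACGAACACGATCTGG
CATTGGGAGACCCCCCCTTGGGGGATGTTCCATGCCTACTGCTGGCAAGAAGAGCACGAAGATAATCATT
GGAAATGGCCATTTGGGTCGAGGCGGAATAGAAAAAATCGTTTCTCGCAACCTTGGGACCGTTCAATGAA
CATGTGGTATTGGGCTTGGATCATGCTTCAGGTAGAAACTTGGCATAGGCGTTACGAACACTTTCCTTTT
ACCCACGAAAAGCCTCACCCCTTTAACGGGTCCTTTATCACCCAGATGCAGGAAATGATGCCGTGTAAAT
TCGATCCAGACCAAGAAACGCACAGCCCCCACTATGGGTGCTGTTTGGATAAAGGACGTGCTTGCTGTTG
GAACAGCCTTCAGAACCGACGCGCATTGGACCTTCTTTTTGCTGAGCGGGGCGGGACGTGGCACTGGCAG
ATAATTGAGAACCATTGTAAAGGCGCATTTCAATATCGGACAGGCCGGAGAATGTTCTCACAGACGCGCC
GGGGAGGTCATTGCCCCCAATGCGCAGATGTGCACGTAAATAGCGTTGTTCAAACGTTTCAGGGATTCTA
CGTTTTTATATCGATGTACACCCTCCATCGGCCGCATCCTAAGGCTTACTTAAAGGACAAGAACTGCGAT
TCGCAATATTGTGAGTCTGCGGCACCACTCCAGAACAAGATGGGCAAGTCTACGAATTCAAAGATGTATC
CTCCACAGGTTGAGAATTGGTGCACGCATATTATGAAACTGAGCTCCCAAGTTCCAAGGCAGATGTATCA
GGACTAA
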