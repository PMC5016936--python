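>W
TCCGGCTCTCTGCGGCCA
>R
CTTCTTGCGGGGCACCCA
>F
GACACGTGCCATGGACCA
>I
TCTAGAATGGAGGTCCCA
>S
AGCGACACTAAAGGACCA
>P
CGGCCCAAGGTTGGACCA
>L
CTTTCCTAAGTAATTCCA
>N
GAGTAAGTCGCCCGACCA
>E
GTATGAAAGTCACACCCA
>G
GGTGCAATAAGGGCCCCA
>K
CTGGCCGGCGTGAGTCCA
>Q
GACTTCAAGACCGCCCCA
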