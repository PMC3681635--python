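>pcr_wt_390bp
GTATCCTCGATGCTCCACACTCCTTGGCATGAGTGTAGCAGTGCTGGTATGTATAATTTC
CAGGTCAGTTACTCGAGTTTGATATATACCGACACCAGCGGCTGTCGATACACTGACCGC
GTGCCCAACCCGTTTTGTGGACAAGTCTGATCCTAGACATCTGGGCCTATTCGCCGACTC
GCATACTCTGTGCTACCCAAGCTGTGGCTCATGTGGAAGGATAGAGCAAAAGCTTTGTTA
ACAGCCCAGGGACGACAAACCTCATAATTCACCTCATGAACAGGATTTGGAAATGTCTAA
CGGCCGTCTACGGCCTGGAAAATACAGAAACGTCCTGATTAGAACGCGATCTGCACCGCA
TATTTGACCGCGACGCATGTCTTTACCGCA
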