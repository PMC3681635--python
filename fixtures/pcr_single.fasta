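>pcr_single_390bp
CTCGACCTGAATGGAAGCCGGCGGCACCTCGCTGACCGATTCACCACTGTATCCTCGATG
CTCCACACTCCTTGGCATGAGTGTAGCAGTGCTGGTATGTATAATTTCCAGGTCAGTTAC
TCGAGTTTGATATATACCGACACCAGCGGCTGTCGATACACTGACCGCGTGCCCAACCCG
TTTTGTGGACAAGTCTGATCCTAGACATCTGGGCCTATTCGCCGACTCGCATACTCTGTG
CTACCCAAGCTGTGGCTCATGTGGAAGGATAGAGCAAAAGCTTTGTTAACAGCCCAGGGA
CGACAAACCTCATAATTCACCTCATGAACAGGATTTGGAAATGTCTAACGGCCGTCTACG
GCCTGGAAAATACAGAAACGTCCTGATTAG
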