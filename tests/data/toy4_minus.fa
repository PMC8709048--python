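>toy4_minus_locus
TTCGCCCCCTTGGATCGAACCGCCCGACGTCAGCAGGTCTAATGAGCGACCTAGAGAAGCAACTGTCTAC
TATAAGACCCGCACGCAACTTGTTCAGTACTTCCGTTCCGACGGTCAGATTCTTGCACGCAACCGAGCCT
TGTTGGACTTAATCTCCCTTGCCCAGCACCTACTCCAGTGAATGTTCTGTAGTGAGGGACGGTCCGCGCT
CCCAAGGTTGTTAGCTACACCTCTGTGTTCTATGCATTAGACTGTTTGTTATCATTATCCCTTGCGAAAC
TGCAGGATGGAGCGGTACTACGCGTTAGTTCAGAGCCGTTGAATAGATAGCCCACGGTACCTGGCCGCAT
TCTTGATCTGTCCATGCATA
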