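name	forward	reverse
ECOR1_FORWARD	GCAGAGCTCGTTTAGTGAACCGTCAGAATT	NA
XHO1_REVERSE	NA	CTGTTCAGGAAACAGCTATGACCGCGGCCG
A230T	GCGAAATTTTACTGACATTGATGATTCCTGG	CAATGTCAGTAAAATTTCGCCAGTGATTGC
E341D	AAGTGTGGGATCGACCTCTCTCAGGCTTAGC	GAGAGGTCGATCCCACACTTCAAAGTTGTCTC
L310F	AGCCAAAGCTTTCCTTCAGGATAAGGACGTA	CCTGAAGGAAAGCTTTGGCTTGAGGGCTGA
V269M	GATATGTTAATGATTGGCAACTTTGGCCTC	TTGCCAATCATTAACATATCTGGGTCATTCC
T410A	ATAAATCCCGCAGGCACTGTTTTGCTTCAG	ACAGTGCCTGCGGGATTTATGTGACTTCTTA
L300F	TCTAATGACTTCCGACACATCAGCCCTCAA	GATGTGTCGGAAGTCATTAGACATGAATAAAG
R301P	TGACCTCCCACACATCAGCCCTCAAGCCA	GGCTGATGTGTGGGAGGTCATTAGACATGAAT
D244H	GTATCTTGCACTGGACATCTTTTAACCAG	GATGTCCAGTGCAAGATACTCTTTATACTTT
Q280K	CTGGAATCAGAAAGTAACTCAGATGGCCCTC	TGAGTTACTTTCTGATTCCAGCTGAGGCCAA
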