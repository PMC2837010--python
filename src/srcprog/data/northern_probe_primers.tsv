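gene	forward_primer	reverse_primer
CD44	TTACTCCGTACTCACATATGCC	CGTCACATGCTCCTGTTCG
DKK3	AAAACCCAGCATACACACTGC	CAGACTTCACACCTGCTTGG
HMOX1	CTGCCCTGGAGAAAGACTTG	AAGCTCTGCCTTTGGCTGTA
ITGA1	CTCTTCTCTACATTACGACG	ATTTTCTTCTTCAGTGGC
ITGA6	GTAATGGCAAATGGCTG	GAACGCTGGAAGAACC
ITGA8	TGGAAAGAGGGAAGAGC	AAGAAGATTGGTGGAAGG
NOV	ATGAAGTGCTCCTGGGAGG	GACATGGGATCTAATGGCTGG
PLCPI	CTCCTCAGAACCACTGCACA	TTCAAGTGTATTTTATTCTCCTGCAT
THBS2	GGGTTATTCGCCACCAAGG	TAGACCTAATCGTCCACCAGC
UPP1	TATGAAGGACAGGGCAGGTT	TTTCAAACGTCACAGCAAGC
VIP	TAGAAAACGAGTTAGCTCCCAGGA	AGAGTTTGCTAGGTGTCCTTCAGA
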