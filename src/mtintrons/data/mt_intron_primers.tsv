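locus	forward	reverse	role	binds_within_intron
ccmFci1	TTTCACATGGAGGAGTGTGC	TTCCCCATATGGAGTTCG	amplification	none
ccmFci1	ATTGGTCAGACGACGACTACT	TCTCTCAGTGTGGTCAGC	sequencing_internal	both
nad1i2	CGATCTGCAGCTCAAATGGT	ACCTACAGCCCTTTCCTCT	amplification	none
nad2i1	GTAATGTGGGTTGGCTTGGA	GCAATAGTTAGGAGAGGTG	amplification	none
nad2i4	CAGTGGGAGTAGTGACTAG	GGAAGTCATTGCTAGTAG	amplification	none
nad4i1	AGGGGCCTTGTGCAGTAAA	CTTTCTTTGTCTCGAACCCC	amplification	forward
nad4i3	GTAGTACCGGTGAACCAGAT	CTTACGGATGTATGCATG	amplification	forward
nad5i1	ATGTTTGATGCTTCTTGGGG	TTAACATCACTACGGTCGGG	amplification	none
nad5i4	GGTATCTCGTACACATTCCG	CCCACATACGAGAAAAGGTC	amplification	none
nad5i4	CAACTAGTATAGTATAGCAG	GGGAATCTAGGAATGAATGG	sequencing_internal	both
nad7i1	AACGGAGAAGTGGTGGAACG	TTTCTCAGTCCCTCTAGTCG	amplification	none
nad7i1	AAGACCGTCTGGCGAAAACG	CGTTTTCGCCAGACGGTCTT	sequencing_internal	both
nad7i2	AGATGCCAGCGGAATGAT	GTGTTCTTGGGCCATCATAG	amplification	none
nad7i3	ATGTTAAGAGGTCGTGCG	AACATCGTAAGGTGCTGCTC	amplification	none
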