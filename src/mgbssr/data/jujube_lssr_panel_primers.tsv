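# Published 12-marker jujube LSSR primer panel: expected amplicon sizes (bp),
# primer sequences (5'-3'; the "forward" oligo carries the M13 tail when ordered),
# core repeat unit and fluorescent dye group.
marker	expected_len	forward	reverse	core_unit	dye
LSSR-4	209	GCCTTCGTCTAATTCCTCTCTGAT	ATGCTGCCAGGAGTGTTCAATA	(GCA)7	ROX
LSSR-6	309	CATTCAGCATCAACAATATCCTCCA	GCTCTATTTCTCTACCATTCTCACACT	(CAT)4	ROX
LSSR-8	252	TAGTCTCTTCTCTGGCTATAC	CCATTGGTAACAGCAAGTT	(GAA)6	TAMRA
LSSR-10	129	GCTCGCCACATAACAGGATACA	GAAAGCCATAACTCGTTGATCTTGT	(CTTG)5	FAM
LSSR-17	141	TGGAGGACTGTTCCTACCAATAC	CAAGAAGATACAAACCCACCAATCA	(GACA)4	HEX
LSSR-22	267	CAAAGACCGAAAGAAAGTTCAGCAA	AACAGACATGGCTATGGTGGAATT	(TTA)6	TAMRA
LSSR-23	217	CAAGATCCAGCCAAAGTCAAAGTTT	ATGAAGTCGTCGCTGTCAAGTG	(TAT)4	ROX
LSSR-25	121	TAGCGTTTGCAGGTTGCTTAGT	CCAGAACTACTCAGAACTTCTATCATC	(AAT)4	FAM
LSSR-26	172	AACAGCATATTTGGATCCATTTCG	GGAAGGACTTTGTCAGCATGGTAG	(GTT)12	HEX
LSSR-27	136	AAAGCATCACCCATCCTCTACATC	CACTGCAAATGCTTTGTCATCTTT	(TATG)6	FAM
LSSR-28	257	TGGTTTTTCTTCTCCTAATCCATGTG	CGTGGACCAAGTCTATACCAAAATG	(ATA)9	TAMRA
LSSR-29	145	TGGGAGTCTAGCTTCATTCAAACA	TCAATAATTCCAGCCGAATCCTTA	(TATA)5	HEX
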