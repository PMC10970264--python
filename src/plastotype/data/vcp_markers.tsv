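Marker	Variation Loci	AlleleFAM	AlleleHEX	Specific Type	Corresponding Alleles of cpGenome Groups	Primer_AlleleFAM	Primer_AlleleHEX	Primer_Common	Flank1	Flank2
CSNP01K	CPMSNP01	T	G	B	T	AGCAATCTGAGTTTTTCATTTTTACTAACTTA	GCAATCTGAGTTTTTCATTTTTACTAACTTC	CTTCATTTACCAAATCCAAAAATTTGGGAA		
CSNP02K	CPMSNP02	A	G	B	A	AACAAACATAAACTAATTAGATAGAAAAGGAGT	CAAACATAAACTAATTAGATAGAAAAGGAGC	GAAAGAAAGGGAGTCTAATCCATAGAACTT		
CSNP03K	CPMSNP03	C	G	T	G	AGGATCCATTTGACCCCCAATATG	AGGATCCATTTGACCCCCAATATC	GGAAAATAAATAGGGGGTACTTCTTTTCTT		
CSNP04K	CPMSNP04	A	G	T	G	AAATAAATAGGGGGTACTTCTTTTCTTTCA	AAATAGGGGGTACTTCTTTTCTTTCG	CTTACAGGATCCATTTGACCCCCAA		
CSNP07K	CPMSNP07	T	G	D	T	GCAGGGGGTAGAAAGGCTGATA	CAGGGGGTAGAAAGGCTGATC	CTACATTGAATGTATAGCTGCAGCAATAAA		
CSNP08K	CPMSNP08	C	A	H	A	AATAAATAAAGGGTTTCAAAAGTCAATTTTTC	AATAAATAAAGGGTTTCAAAAGTCAATTTTTA	GGAATTCTGAAAAAAAAAAGAAAGATATTG		
CSNP09K	CPMSNP09	C	T	H	T	TCAACGTCCAATTATGAAATCCTTGG	GTTCAACGTCCAATTATGAAATCCTTGA	GTAGCAGCTATATTTCGGTTCATCCTTT		
CSNP10K	CPMSNP10	C	A	H	A	ATATTTTATAGGGTATATCCACCTGG	CCTATATTTTATAGGGTATATCCACCTGT	ACATAGACGGTCGACCCAGACATA		
CSNP12K	CPMSNP12	T	C	H	C	TTTCTTTCATTTTTTTTTTTTTTTTTTCT	GCTTTTCTTTCATTTTTTTTTTTTTTTTTTCC	TATCCAACCCTTTTTTTTTATTTAGCAGGC		
CSNP16K	CPMSNP16	A	G	B	A	ATGTAGGATATGCTTTTTATTTTTTGTTGGA	GTAGGATATGCTTTTTATTTTTTGTTGGG	CTGCAGAGTATCAAAATTATACTACTGCCT		
CSNP17K	CPMSNP17	C	T	B	C	AAATTCATTCATTTCTTTTTTGAAAATGTCC	CTAAATTCATTCATTTCTTTTTTGAAAATGTCT	GGCATCTCGCACTAAACTAAGTCATAAA		
CSNP18K	CPMSNP18	T	G	C	G	GTGCTCGTTTAGTGTTCAGACCA	GTGCTCGTTTAGTGTTCAGACCC	CTTAGTTTAGTGCGAGATGCCCACAT		
CSNP19K	CPMSNP19	A	C	D	C	AGTTGATGGTTAGGTTAATTCACGGAT	GTTGATGGTTAGGTTAATTCACGGAG	TAACCTTAAAAAGCTTAAAAAGTAGGGGAT		
CSNP21K	CPMSNP21	A	C	/	/	GGTTTTTTCCTTTTACTTTTTTTCTTTTACTAT	GGTTTTTTCCTTTTACTTTTTTTCTTTTACTAG	GAGAAAAATAATACGAGAATAGACTAGAAT		
CSNP22K	CPMSNP22	A	G	/	/	CCTTTTTTAAGCATGAAAGATTCGTAGGT	CTTTTTTAAGCATGAAAGATTCGTAGGC	CGAGAATAGACTAGAATAGATTATAGTAAA		
CSNP26K	CPMSNP26	A	G	H	G	ACTTACTTTTTTAGAATCTTTTTCAAAAAATA	ACTTACTTTTTTAGAATCTTTTTCAAAAAATG	AGCGAAACTGGATCCAAAAAAGCAGAAAT		
CSNP28K	CPMSNP28	T	G	H	G	ATTTATTCTTATTCTATTTTATTATGCCATTCA	TATTCTTATTCTATTTTATTATGCCATTCC	TCTTAAATCGGTATTCCCCCCCATTATTT		
CSNP29K	CPMSNP29	G	T	T	T	ATATTCTAAAAAGATTGGATAGCAAAGATTTC	GATATTCTAAAAAGATTGGATAGCAAAGATTTA	GCTTTATCCCGTTTCATAGAAAGGAGATA		
CSNP30K	CPMSNP30	A	G	B	A	TAGGAAATCGCGAATTAGATCATTTGTTT	GGAAATCGCGAATTAGATCATTTGTTC	GCTCGTGCTTCTCTTGTTGAGGTAA		
CSNP31K	CPMSNP31	T	G	H	G	TTAAGTATACATAAAGCAATTTTTTTTACTTT	TAAGTATACATAAAGCAATTTTTTTTACTTG	GTTAGCATTCTAAGGTCAAAAGTATAGTTT		
CSNP33K	CPMSNP33	T	G	H	G	ACTGACTTCTTTTACTTATTAAAATACAATTTA	ACTGACTTCTTTTACTTATTAAAATACAATTTC	CTAACAGGTCTGATTTTCGATTTTGTACTT		
CSNP37K	CPMSNP37	C	T	H	T	CAATTTTTATCAGAGGACAATATGAATATTAC	CAATTTTTATCAGAGGACAATATGAATATTAT	TATAACCCCTTGAGTGTTTTAATGGAACAT		
CSNP38K	CPMSNP38	G	A	C	A	ATTCTAAAATCATTCTTTAGAAAGCCACAC	CTAAAATCATTCTTTAGAAAGCCACAT	GGCCAAGTCAGGTTAGATCTATATCTTTA		
CSNP39K	CPMSNP39	A	C	C	C	ATGGGAACTCAAAGATATCGAAGAGTA	GGGAACTCAAAGATATCGAAGAGTC	CAACCAATCACTCTTTTATTCCATCCTTTT		
CSNP40K	CPMSNP40	A	T	B	A	CTATCAATTTTTATTTTCCATTTATTTAGTTA	CTATCAATTTTTATTTTCCATTTATTTAGTTT	GTTTCTTTATTTGTGTTTGCTCTGTTAGTT		
CSNP41K	CPMSNP41	A	T	/	/	TTATGATCTCTTCCCGAACCAAACAT	TATGATCTCTTCCCGAACCAAACAA	CGGGAGAGCCAAATGAATCGAAAGAT		
CSNP44K	CPMSNP44	A	C	C	C	GCCTATACTACTATTCTATGGATAAAGCT	CCTATACTACTATTCTATGGATAAAGCG	TCGCTCACTAATTGATCTTTACGGTGTTT		
CSNP45K	CPMSNP45	T	G	H	G	AAGCGCGGGTTTCCTTTACTAATTTT	AGCGCGGGTTTCCTTTACTAATTTG	AGAGAGAGGGTTCGCATAGAGAGAA		
CSNP47K	CPMSNP47	T	G	T	G	GAACTATTTATCCTTAAATTATTAACAAATAA	GAACTATTTATCCTTAAATTATTAACAAATAC	GCCAAGAGATTGGCATTTTCATTTGATCAT		
CSNP48K	CPMSNP48	T	A	C	A	ATCCTCGTCCGATTAATCCACTTTTA	ATCCTCGTCCGATTAATCCACTTTTT	CCTTCAATTCATTGTTTTCGAGATCTTTTA		
CSNP49K	CPMSNP49	T	G	H	G	AGTGAATCTTAAACCCATTGATAAAAGA	AGTGAATCTTAAACCCATTGATAAAAGC	TTTATTCCCTAACCATAGTTGTTATCCTTT		
CSNP52K	CPMSNP52	C	T	H	T	CCAAAAGGATAATCCTAGAATCCCG	CCCAAAAGGATAATCCTAGAATCCCA	ATCGGCACTTCTCCAAACCCAGAAA		
CSNP56K	CPMSNP56	A	C	/	/	CCTATTTTAATATATATTAATCATCCTATTTT	CCTATTTTAATATATATTAATCATCCTATTTG	ACTTACTACTAATTGGATTAGAACCTAATT		
CSNP57K	CPMSNP57	G	A	C	A	TATTTAGTACTTGTTTATAGACTCGAC	CCTTATTTAGTACTTGTTTATAGACTCGAT	AATGCTTTTATCTCTATTCTATGGCGCAAT		
CSNP58K	CPMSNP58	A	T	B	A	CAACAAGGTCAATTATGTTCATTGCATAAA	CAACAAGGTCAATTATGTTCATTGCATAAT	GCGCCAATGCTTTTCAAGGGAACTT		
CSNP59K	CPMSNP59	G	A	C	A	ATTCAACAAGAAAAAAAATTTCGACAAATTCC	ATTCAACAAGAAAAAAAATTTCGACAAATTCT	GCGAAGTAGTAGGATTGGTTCTCATAATT		
CSNP60K	CPMSNP60	A	T	H	T	GATTCAAAATATCAAAGGGGAAGAACTTTA	CAAAATATCAAAGGGGAAGAACTTTT	GCAACCCAAACCCTAATCTTTATTTTACAA		
CSNP62K	CPMSNP62	T	G	/	/	AAAGAAATACCTCTTTCAGAATACCCTTTA	GAAATACCTCTTTCAGAATACCCTTTC	CAACTGGGTATTCTATTCCACTTCTACTT		
CSNP64K	CPMSNP64	A	G	/	/	AATTAGCATATTTCTTTTCTTCCTTTAGAAATA	AATTAGCATATTTCTTTTCTTCCTTTAGAAATG	ATTTTGTTAAAAAGGAAAAGGGCTTTCTTT		
CSNP65K	CPMSNP65	G	A	H	A	CGATTTCTGTATCGATCATGATATACG	ATCGATTTCTGTATCGATCATGATATACA	GATATGCGTTTGAAATAGATGTGCGAGTT		
CSNP66K	CPMSNP66	C	T	H	T	TATTTGTTTTGTCAAAGATTACTATTTATTC	CTTATTTGTTTTGTCAAAGATTACTATTTATTT	GGAAGTCCAAAAGACAGACCCGAAT		
CSNP67K	CPMSNP67	A	C	T	C	AGTTGAACTTAATTCAAAAAGTAAAGCAATTCT	GTTGAACTTAATTCAAAAAGTAAAGCAATTCG	CGGGGACACATTTCTTGTGAGCAAA		
CSNP69K	CPMSNP69	T	A	B	T	CCCCTCAAAAAGGGAACTATTCCTA	CCCCTCAAAAAGGGAACTATTCCTT	CCACTTTTGTTGGGGTTCAAAAAACGAAT		
CSNP72K	CPMSNP72	T	C	C	C	TCATATACTAAAAAAGAATTCAAAAAGGGGA	CATATACTAAAAAAGAATTCAAAAAGGGGG	GAGATAGAATTCTTCGTGACATGACGAAA		
CSNP73K	CPMSNP73	T	C	T	C	ATTTCAAAAATTTTGTATTCTATTGGATTGGAT	TCAAAAATTTTGTATTCTATTGGATTGGAC	TTTGTTGTAATTCTTCGAATTCTCGAACAA		
CSNP74K	CPMSNP74	T	G	B	T	TGTATTCTATTGGATTGGATTTGTTCGAT	GTATTCTATTGGATTGGATTTGTTCGAG	TCTAAAGATTTTGTTGTAATTCTTCGAATT		
CSNP79K	CPMSNP79	G	T	H	T	GTATTTCTATTTTCTATAGCATAAAACCCG	AAGTATTTCTATTTTCTATAGCATAAAACCCT	GGATTTCTTGTAAATTTATCTCAAACCTAA		
CSNP81K	CPMSNP81	G	A	C	A	AGGCGTGGGCGAATTAGAGTC	CAGGCGTGGGCGAATTAGAGTT	GTCTTTGTTTATGCTTCGGATTGGAACAA		
CSNP83K	CPMSNP83	T	A	B	T	TAGTAGATTTTGTCTCACGTATATGCTTA	AGTAGATTTTGTCTCACGTATATGCTTT	CATGTTTTCCCTTTTCTTTAAATTTAGGAT		
CSNP85K	CPMSNP85	G	T	/	/	TTTTCTTTTTTAAGTTTAAGAAAGTCAAAATC	TTTCTTTTTTAAGTTTAAGAAAGTCAAAATA	CACATCAATATATAATAGAAAAAGTTAGGT		
CSNP86K	CPMSNP86	A	C	T	C	TTGAATCCTGCAATGGAGCTTCCA	GAATCCTGCAATGGAGCTTCCC	GCAGCCGGGTTAATAAAACTGAGAAAATT		
CSNP91K	CPMSNP91	A	C	/	/	ATACTGAAAGATACTGAAAGATACTTAAATTCT	CTGAAAGATACTGAAAGATACTTAAATTCG	CCACATTAGACAAAATGAACTAAAGAAGAA		
CSNP92K	CPMSNP92	C	T	B	C	CTTGCAATAGGACTTACAACCTCC	CTTGCAATAGGACTTACAACCTCT	CCCATTTATATGGGAATTTTGGATAAGATT		
CSNP93K	CPMSNP93	T	A	B	T	CCAATTTCACCATGGCGGCTAATTTA	CCAATTTCACCATGGCGGCTAATTTT	CCCAGTCTCGACGATTCACGATAAA		
CSNP95K	CPMSNP95	A	G	/	/	AAAAGATATGGAATACAATACAAAAAAGGATCT	AGATATGGAATACAATACAAAAAAGGATCC	GAATAGGGATAAAGGAAGGAAAGAATAAAT		
CSNP96K	CPMSNP96	A	G	H	G	AAAAGATCCTATTTTAACGAATCACACGTA	AGATCCTATTTTAACGAATCACACGTG	TACCATTAACTTTTTGTGTACTAGCAATAT		
CIDP01K	CPMIDP01	ACTGTATACACGGATACAGAATCCGCTATATCCGTTTGTGAAATAAAGGCTAAATCCCCTCCCCTCAACTCCATATCTAAATA	-	H	I	TTTTATTAAAACTTTTTCCTTACCGCTTTTA	CTTTTTATTAAAACTTTTTCCTTACCGCTTTTT		ATGCAAGTCCACTTTCAATATATCTCTGTA	CCCTCCCCTCAACTCCATATCTAAA
CIDP02K	CPMIDP02	-	TCTTT	H	D	CAAGTTTGAAAGATTGTACTGCTCTTTC	GCAAGTTTGAAAGATTGTACTGCTCTTTT	ATTAGGAGGGGTTCTTTTGTGCAGAAAAA		
CIDP04K	CPMIDP04	-	ATGAACTTCTAATG	/	/	AGAATTTAGGAACATTAGAAGTTCATCATTAA	GAATTTAGGAACATTAGAAGTTCATCATTAG	TCTAAAATACAAAATGCATTTCATTGTAG		
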