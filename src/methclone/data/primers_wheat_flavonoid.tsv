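gene	forward	reverse	expected_bp	annealing_c
TaCHI-A1	TTATTAATTAAGTAGAAAAGAATTGTTTAGTTAA	TAAAAACRTAATTAATAATAATTAAAAAAAACAC	374	50
TaCHI-A1	GTTTTTGYGTGAGTTGAATGGTAG	ACRAAATAATCAACTAAAATAATAATACC	298	50
TaCHI-A1	GGAGAGGGTATTATTATTTTAGTTG	AAACCRTTAACTAAATAATCACCTAC	273	50
TaCHI-B1	TTTGATTATTGTTATTTTTATTTTAAATATGTATGT	ATATAAAAACRTAATTAATAATAATTAAAAAAAACA	436	50
TaCHI-B1	TYGTAGGGTGGTTTTTTTTGAGA	TAACRAACAAACACTTATATTAATAAAAC	464	50
TaCHI-B1	AGTTGTTGYGGTGTTATATAGGG	ACCAAATACRTTAAAACAAAATCTAAAATC	343	53
TaCHI-D1	TATATTTTATAAGGTGGTTTTTTTAATTTTGTTGAG	TAAAAACRTAATTAATAATAATTAAAAAAAACAC	320	53
TaCHI-D1	GTGYGTGAGTTGAATGGTAGTTTG	TAATAATACRTACCCCCCCTATATAACACC	294	55
TaCHI-D1	GYGTAGGTTAGAGAATTAGATTAG	AAATAAACRTACTCRAAACCCRAC	326	50
TaF3H-B1	ATGATGTATAGGTTTTAGATATTGGG	ATATACRCACAACACACACATCAC	400	53
TaF3H-B1	ATATGAGYGTTTGTATTTGGATTGTG	CTCRTATAATAATTTATTCCTTAATAAAAAACTC	365	53
TaF3H-B1	TAAAYGGTYGAGTTTTTTATTAAGGAATAAATTATT	TCRAAAAAAACRTCTCGTTACTCACC	125	53
TaF3H-B2	GYGAGTTTAGATGGTTAGATATTTTTTGT	CACTAAATAAACATCACCAAAAAATCTAAAAT	410	53
TaF3H-B2	TTATTTTAGATTTTTTGGTGATGTTTATTTA	AAACAAAAACATCCTATTACTCAC	222	50
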