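name	pattern	function	place_id
ABRELATERD1	ACGTG	Element required for etiolation-induced expression of genes responsive to dehydration	S000414
ACGTATERD1	ACGT	Sequence required for etiolation-induced expression	S000415
CBFHV	RYCGAC	Dehydration-responsive element	S000497
CGACGOSAMY3	CGACG	Coupling element for the G box element	S000205
CGCGBOXAT	VCGCGB	Element in promoters of many genes	S000501
CRTDREHVCBF2	GTCGAC	Core CRT/DRE motif	S000411
HEXAMERATH4	CCGTCG	Hexamer motif of the histone H4 promoter	S000146
MYBCORE	CNGTTR	Binding site for animal and plant MYB proteins	S000176
SORLIP2AT	GGGCC	Sequences over-represented in light-induced promoters	S000483
SURECOREATSULTR11	GAGAC	Core of sulfur-responsive element	S000499
DRECRTCOREAT	RCCGAC	Core motif of dehydration-responsive element / C-repeat cis-acting element	S000418
LTRECOREATCOR15	CCGAC	Core of low temperature-responsive element	S000153
MYB2CONSENSUSAT	YAACKG	MYB recognition site	S000409
MYBCOREATCYCB1	AACGG	Myb core	S000502
PALBOXAPC	CCGTCC	Box A	S000137
ABRERATCAL	MACGYGB	Repeated sequence motif in upstream regions of calcium-responsive upregulated genes	S000507
ARFAT	TGTCTC	Auxin response factor binding site of primary/early auxin response genes	S000270
CURECORECR	GTAC	Core of a copper-response element	S000493
DOFCOREZM	AAAG	Core site required for binding of Dof proteins	S000265
DPBFCOREDCDC3	ACACNNG	Binding core sequence of bZIP transcription factors	S000292
GATABOX	GATA	Motif required for high-level, light-regulated, and tissue-specific expression	S000039
LTRE1HVBLT49	CCGAAA	Low-temperature-responsive element	S000250
MYBST1	GGATA	Core motif of MYB binding site	S000180
NODCON2GM	CTCTT	Putative nodulin consensus sequence	S000462
OSE2ROOTNODULE	CTCTT	Organ-specific element of promoters activated in infected root-nodule cells	S000468
RHERPATEXPA7	KCACGW	Right part of root hair-specific cis-elements	S000512
SEBFCONSSTPR10A	YTGTCWC	Binding site of the silencing element binding factor in a pathogenesis-related promoter	S000391
ERELEE4	AWTTCAAA	Ethylene responsive element	S000037
REALPHALGLHCB21	AACCAA	Motif required for phytochrome regulation; DNA binding activity high in etiolated plants	S000362
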