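triplet	helix	fwd_primer	fwd_ndn	rev_primer	rev_ndn
GAA	QSGNLAR	CaaTCGGgTaacCTTgCCCGCCATATCCG	7	GGCGGGCAAGgTTAcCCGAttGACTGAAG	4
GAC	DRSNLTR	gaCagGagTaatCTTACCCGCCATATCCG	9	GGCGGGtAAGATTActCcTGtcACTGAAG	6
GAG	RSDNLAR	CGCTCGGATaatCTTgCCCGCCATATCCG	4	GGCGGGCAAGATTATCCGAGCGACTGAAG	0
GAT	TSGNLVR	acCTCGGgTaatCTTgtCCGCCATATCCG	8	GGCGGaCAAGATTAcCCGAGgaACTGAAG	4
GCA	QSGDLTR	CaaTCGGgTGatCTTACCCGCCATATCCG	5	GGCGGGtAAGATcAcCCGAttGACTGAAG	4
GCC	DCRDLAR	gaCTGcagaGacCTTgCCCGCCATATCCG	9	GGCGGGCAAGgTctctgcAGtaACTGAAG	9
GCG	RSDDLQR	CGCTCGGATGacCTTcaaCGCCATATCCG	5	GGCGttgAAGgTcATCCGAGCGACTGAAG	5
GGA	QSGHLQR	CagTCGGgTcatCTTcaaCGCCATATCCG	9	GGCGttgAAGATgAcCCGActGACTGAAG	7
GGG	RSDHLSR	CGCTCGGATcacCTTtCCCGCCATATCCG	4	GGCGGGaAAGgTgATCCGAGCGACTGAAG	3
GGT	TSGHLVR	acCTCGGgTcacCTTgtCCGCCATATCCG	8	GGCGGaCAAGgTgAcCCGAGgtACTGAAG	6
GTC	DPGALVR	gaCcCGGgTGCGCTTgtCCGCCATATCCG	6	GGCGGaCAAGcgcAtCCGgGtcACTGAAG	8
GTG	RSDALTR	CGCTCGGATGCGCTTACCCGCCATATCCG	0	GGCGGGtAAGcgcATCCGAGCGACTGAAG	4
GTT	TSGSLVR	acCTCGGgTtCGtTagtCaGaCATATCCG	10	GtCtGaCtAacgaATCCGAGgtACTGAAG	10
AAG	RKDNLKN	CGCaaGGATaacCTTAaaaaCCATATCCG	9	GGtttttAAGgTTATCCttGCGACTGAAG	8
ACT	THLDLIR	acCcacctTGatCTTAtCCGCCATATCCG	10	GGCGGatAAGATcAaggtgGgtACTGAAG	10
AGA	QLAHLRA	CaaTtGGcTcacCTTcgCgcCCATATCCG	11	GGgcGcgAAGgTgAgCCaAttGACTGAAG	10
AGG	RSDHLTN	CGCTCGGATcacCTTACCaaCCATATCCG	5	GGttGGtAAGgTgATCCGAGCGACTGAAG	5
ATG	RRDELNV	CGCcgGGATGaGCTTAACgtCCATATCCG	5	GGacGttAAGcTcATCCcgGCGACTGAAG	8
CTG	RNDALTE	CGCaatGAcGCGCTTACCgaaCATATCCG	7	GttcGGtAAGcgcgTCattGCGACTGAAG	11
TGA	QAGHLAS	CaagCGGgTcatCTTgCCaGCCATATCCG	9	GGCtGGCAAGATgAcCCGcttGACTGAAG	6
TGG	RSDHLTT	CGCagtGATcacCTTACCacCCATATCCG	8	GGgtGGtAAGgTgATCactGCGACTGAAG	8
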