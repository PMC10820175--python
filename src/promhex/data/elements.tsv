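name	iupac	source
DRE	RCCGAC	external-literature, editable: classical CRT/DRE core bound by DREB factors
DRE-like	CCTACC	study: DRE-like hexamer enriched under salt stress
CCCCAC	CCCCAC	study: DRE-like hexamer enriched under osmotic and salt stress
ARR1AT	GTKATT	study: printed variants GTTATT (osmotic) and GTGATT (salt)
MYBST1	TATCCC	study: top-10 hexamer under osmotic stress
BOXIII	CATTT	study: top-10 element under osmotic stress
New3	CGTCCA	study: novel element, strong yeast one-hybrid binding
New4	TTCTCT	study: frequent in lignin/starch/sucrose pathway promoters
CATTTT	CATTTT	study: frequent in pathway promoters
AAACAA	AAACAA	study: frequent in pathway promoters
TTTCTC	TTTCTC	study: frequent in pathway promoters
TCTTTT	TCTTTT	study: frequent in pathway promoters
GCC	GCCGCC	external-literature, editable: GCC-box, ERF-binding element
ABRE	ACGTGKC	external-literature, editable: ABA-responsive element core
MYBCORE	CNGTTR	external-literature, editable: MYB recognition core
AuxRR	GGTCCAT	external-literature, editable: auxin-response region core
CE3	ACGCGTG	external-literature, editable: coupling element 3 core (approximate)
obo-Box	-	bait name only; sequence not printed here — editable
New1	-	bait name only; sequence not printed here — editable
New2	-	bait name only; sequence not printed here — editable
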