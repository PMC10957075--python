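# Antibody Liability Reference, v1
# Columns: tag	name	severity	pattern	scope	rule_kind
# Patterns use single-letter amino-acid codes, bracketed classes, one-level
# negation ([^P]) and top-level alternation. Positional-cysteine rules carry
# no pattern. Scope "cdrs" restricts reporting to matches touching a CDR;
# scope "fv" reports matches anywhere in IMGT 1-128.
DeAmdH	Deamidation (high)	high	N[GS]	cdrs	motif_scan
FragH	Fragmentation (high)	high	DP	cdrs	motif_scan
Isom	Isomerization	high	D[DGHST]	cdrs	motif_scan
mCys	Missing Cys	high		fv	conserved_cys_missing
xCys	Extra Cys	high		fv	conserved_cys_extra
Ngly	N-linked glycosylation	high	N[^P][ST]	fv	motif_scan
DeAmdM	Deamidation (medium)	medium	N[AHNT]	cdrs	motif_scan
Hydro	Hydrolysis	medium	NP	cdrs	motif_scan
FragM	Fragmentation (medium)	medium	TS	cdrs	motif_scan
TrpOx	Trp oxidation	medium	W	cdrs	motif_scan
MetOx	Met oxidation	medium	M	cdrs	motif_scan
DeAmdL	Deamidation (low)	low	[STK]N	cdrs	motif_scan
IntBind	Integrin binding	low	GPR|RGD|RYD|LDV|DGE|KGD|NGR	fv	motif_scan
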