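level	group	n_species	trait	kind	lo	hi	members	partial	provenance
genus	Alcolapia	4	#Lt	int_set			4,5	0	four lacrimal tubules shared with the fossil; five as standard configuration
genus	Alcolapia	4	lacrimal_depth_pctHL	interval	19	24		0	lacrimal depth 19-24% of head length at 95-130 mm SL (Trewavas 1983)
genus	Alcolapia	4	flank_scale_wl_ratio	interval	1.0	1.3		0	round flank scales with width/length ratio 1.0 occur in A. grahami and A. latilabris
genus	Alcolapia	4	belly_scales	cat_set			very small,small	0	small to minute belly scales (Seegers & Tichy 1999)
genus	Alcolapia	4	supraneural_shape	cat_set			straight,slightly curved,club-shaped	1	thickened distal flange present in some A. alcalica and A. grahami
genus	Oreochromis	32	#Lt	int_set			4,5	0	four lacrimal tubules shared with the fossil; five as standard configuration
genus	Oreochromis	32	lacrimal_depth_pctHL	interval	12	29		1	18-29% of head length at 100-200 mm SL; O. amphimelas 12.5-17% at 82-270 mm SL judged very similar to a 12% fossil value, hence lower bound extended to 12 and flagged partial (Trewavas 1983)
genus	Oreochromis	32	flank_scale_wl_ratio	interval	1.1	1.4		0	moderately rounded to ovate flank scales; ratio 1.0 not recorded
genus	Oreochromis	32	notch_on_cleithrum	cat_set			present	0	acute notch in posteroventral edge of dorsal cleithrum plate (Murray & Stewart 1999)
genus	Oreochromis	32	supraneural_shape	cat_set			straight,club-shaped	0	sharply angled, distally thickened supraneural in O. chungruruensis and O. mossambicus
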