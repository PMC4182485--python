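reporter_id	site_class	cognate_hairpin	cognate_arm	cognate_shift	cognate_seed	n_tandem	control_id	site_window
miR-371-5p-P	perfect	miR-371	5p	0		1
miR-372-5p-P	perfect	miR-372	5p	0		1
miR-373-5p-P	perfect	miR-373	5p	0		1
miR-371-3p-P	perfect	miR-371	3p	0		1
miR-372-3p-P	perfect	miR-372	3p	0		1
miR-373-3p-P	perfect	miR-373	3p	0		1
2-7C-S	seed_only	miR-371	3p	0	AAGUGCC	4	3-7C-S
3-7C-S	mismatch_control					4
3-7CG-B	bulge	miR-371	3p	1	AGUGCCG	4	4-7CG-B
4-7CG-B	mismatch_control					4
4-7CGC-B	bulge	miR-371	3p	2	GUGCCGC	4	5-7CGC-B
5-7CGC-B	mismatch_control					4
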