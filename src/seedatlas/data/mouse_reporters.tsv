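reporter_id	site_class	cognate_hairpin	cognate_arm	cognate_shift	cognate_seed	n_tandem	control_id	site_window
miR-290-5p-P	perfect	miR-290	5p	0		1
miR-291a-5p-P	perfect	miR-291a	5p	0		1
miR-291b-5p-P	perfect	miR-291b	5p	0		1
miR-292-5p-P	perfect	miR-292	5p	0		1
miR-293-5p-P	perfect	miR-293	5p	0		1
miR-294-5p-P	perfect	miR-294	5p	0		1
miR-295-5p-P	perfect	miR-295	5p	0		1
miR-290-3p-P	perfect	miR-290	3p	0		1
miR-291a-3p-P	perfect	miR-291a	3p	0		1
miR-291b-3p-P	perfect	miR-291b	3p	0		1
miR-292-3p-P	perfect	miR-292	3p	0		1
miR-293-3p-P	perfect	miR-293	3p	0		1
miR-294-3p-P	perfect	miR-294	3p	0		1
miR-295-3p-P	perfect	miR-295	3p	0		1
2-7C-S	seed_only	miR-292	3p	0	AAGUGCC	4	3-7C-S
2-7U-S	seed_only				AAGUGCU	4	3-7U-S
2-7G-S	seed_only				AAGUGCG	4
2-7A-S	seed_only				AAGUGCA	4
3-7C-S	mismatch_control					4
3-7U-S	mismatch_control					4
3-7CG-S	seed_only	miR-292	3p	1	AGUGCCG	4	4-7CG-S
4-7CGC-S	seed_only	miR-293	3p	2	GUGCCGC	4	5-7CGC-S
3-7UA-S	seed_only	miR-295	3p	1	AGUGCUA	4
4-7CG-S	mismatch_control					4
5-7CGC-S	mismatch_control					4
3-7CG-B	bulge	miR-292	3p	1	AGUGCCG	4	4-7CG-B
4-7CGC-B	bulge	miR-293	3p	2	GUGCCGC	4	5-7CGC-B
4-7CG-B	mismatch_control					4
5-7CGC-B	mismatch_control					4
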