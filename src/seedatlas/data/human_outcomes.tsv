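reporter_id	background	construct	construct_target	ratio
miR-371-5p-P	KO	full_cluster		0.25
miR-371-5p-P	KO	empty_vector		0.95
miR-372-5p-P	KO	full_cluster		0.9
miR-372-5p-P	KO	empty_vector		1.0
miR-373-5p-P	KO	full_cluster		0.88
miR-373-5p-P	KO	empty_vector		0.97
miR-371-3p-P	KO	full_cluster		0.3
miR-371-3p-P	KO	delta_hairpin	miR-371	0.9
miR-371-3p-P	KO	single_hairpin	miR-371	0.3
miR-371-3p-P	KO	empty_vector		1.0
miR-372-3p-P	KO	full_cluster		0.2
miR-372-3p-P	KO	empty_vector		0.92
miR-373-3p-P	KO	full_cluster		0.24
miR-373-3p-P	KO	empty_vector		0.96
2-7C-S	KO	full_cluster		0.3
2-7C-S	KO	delta_hairpin	miR-371	0.3
2-7C-S	KO	single_hairpin	miR-371	0.9
2-7C-S	KO	empty_vector		0.95
3-7C-S	KO	full_cluster		0.88
3-7C-S	KO	delta_hairpin	miR-371	0.9
3-7C-S	KO	single_hairpin	miR-371	0.95
3-7C-S	KO	empty_vector		1.0
3-7CG-B	KO	full_cluster		0.22
3-7CG-B	KO	delta_hairpin	miR-371	0.95
3-7CG-B	KO	single_hairpin	miR-371	0.25
3-7CG-B	KO	empty_vector		0.97
4-7CG-B	KO	full_cluster		0.8
4-7CG-B	KO	delta_hairpin	miR-371	0.9
4-7CG-B	KO	single_hairpin	miR-371	0.85
4-7CG-B	KO	empty_vector		0.95
4-7CGC-B	KO	full_cluster		0.25
4-7CGC-B	KO	delta_hairpin	miR-371	0.92
4-7CGC-B	KO	single_hairpin	miR-371	0.28
4-7CGC-B	KO	empty_vector		1.0
5-7CGC-B	KO	full_cluster		0.9
5-7CGC-B	KO	delta_hairpin	miR-371	0.94
5-7CGC-B	KO	single_hairpin	miR-371	0.91
5-7CGC-B	KO	empty_vector		0.98
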