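reporter_id	background	construct	construct_target	ratio
miR-290-5p-P	WT	none		0.18
miR-290-5p-P	KO	empty_vector		0.97
miR-290-5p-P	KO	full_cluster		0.21
miR-291a-5p-P	WT	none		0.88
miR-291a-5p-P	KO	empty_vector		0.95
miR-291a-5p-P	KO	full_cluster		0.9
miR-291b-5p-P	WT	none		0.93
miR-291b-5p-P	KO	empty_vector		1.02
miR-291b-5p-P	KO	full_cluster		0.96
miR-292-5p-P	WT	none		0.22
miR-292-5p-P	KO	empty_vector		0.99
miR-292-5p-P	KO	full_cluster		0.25
miR-293-5p-P	WT	none		0.86
miR-293-5p-P	KO	empty_vector		0.94
miR-293-5p-P	KO	full_cluster		0.89
miR-294-5p-P	WT	none		0.91
miR-294-5p-P	KO	empty_vector		1.05
miR-294-5p-P	KO	full_cluster		0.93
miR-295-5p-P	WT	none		0.84
miR-295-5p-P	KO	empty_vector		0.92
miR-295-5p-P	KO	full_cluster		0.87
miR-290-3p-P	WT	none		0.89
miR-290-3p-P	KO	empty_vector		0.98
miR-290-3p-P	KO	full_cluster		0.92
miR-291a-3p-P	WT	none		0.2
miR-291a-3p-P	KO	empty_vector		0.96
miR-291a-3p-P	KO	full_cluster		0.23
miR-291b-3p-P	WT	none		0.9
miR-291b-3p-P	KO	empty_vector		1.01
miR-291b-3p-P	KO	full_cluster		0.94
miR-292-3p-P	WT	none		0.15
miR-292-3p-P	KO	empty_vector		0.93
miR-292-3p-P	KO	full_cluster		0.17
miR-293-3p-P	WT	none		0.19
miR-293-3p-P	KO	empty_vector		0.97
miR-293-3p-P	KO	full_cluster		0.22
miR-294-3p-P	WT	none		0.13
miR-294-3p-P	KO	empty_vector		0.95
miR-294-3p-P	KO	full_cluster		0.16
miR-295-3p-P	WT	none		0.17
miR-295-3p-P	KO	empty_vector		0.99
miR-295-3p-P	KO	full_cluster		0.2
2-7C-S	WT	none		0.25
2-7C-S	KO	empty_vector		0.95
2-7C-S	KO	full_cluster		0.28
2-7C-S	KO	delta_hairpin	miR-292	0.33
2-7C-S	KO	single_hairpin	miR-292	0.3
2-7C-S	KO	single_hairpin	miR-294	0.27
2-7U-S	WT	none		0.2
2-7U-S	KO	empty_vector		1.0
2-7U-S	KO	full_cluster		0.22
2-7G-S	WT	none		0.92
2-7G-S	KO	empty_vector		0.97
2-7A-S	WT	none		0.88
2-7A-S	KO	empty_vector		0.96
3-7C-S	WT	none		0.85
3-7C-S	KO	empty_vector		0.93
3-7C-S	KO	full_cluster		0.9
3-7C-S	KO	delta_hairpin	miR-292	0.92
3-7C-S	KO	single_hairpin	miR-292	0.88
3-7C-S	KO	single_hairpin	miR-294	0.95
3-7U-S	WT	none		0.9
3-7U-S	KO	empty_vector		1.02
3-7CG-S	WT	none		0.72
3-7CG-S	KO	empty_vector		0.98
3-7UA-S	WT	none		0.91
3-7UA-S	KO	empty_vector		0.94
4-7CGC-S	WT	none		0.78
4-7CGC-S	KO	empty_vector		0.95
4-7CG-S	WT	none		0.96
4-7CG-S	KO	empty_vector		1.0
5-7CGC-S	WT	none		0.97
5-7CGC-S	KO	empty_vector		1.05
3-7CG-B	WT	none		0.2
3-7CG-B	KO	empty_vector		0.96
3-7CG-B	KO	full_cluster		0.24
3-7CG-B	KO	delta_hairpin	miR-292	0.85
3-7CG-B	KO	single_hairpin	miR-292	0.27
4-7CG-B	WT	none		0.7
4-7CG-B	KO	empty_vector		0.95
4-7CG-B	KO	full_cluster		0.74
4-7CG-B	KO	delta_hairpin	miR-292	0.9
4-7CG-B	KO	single_hairpin	miR-292	0.8
4-7CGC-B	WT	none		0.22
4-7CGC-B	KO	empty_vector		0.99
4-7CGC-B	KO	full_cluster		0.25
4-7CGC-B	KO	delta_hairpin	miR-293	0.88
4-7CGC-B	KO	single_hairpin	miR-293	0.3
5-7CGC-B	WT	none		0.93
5-7CGC-B	KO	empty_vector		1.0
5-7CGC-B	KO	full_cluster		0.95
5-7CGC-B	KO	delta_hairpin	miR-293	0.97
5-7CGC-B	KO	single_hairpin	miR-293	0.96
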