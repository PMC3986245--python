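snp_id	trait	effect
snp_c5_00017	BW	-0.0477893
snp_c24_00004	BW	-0.447751
snp_c3_00006	BW	-0.0514102
snp_c7_00010	BW	-0.191783
snp_c6_00000	BW	0.736577
snp_c12_00014	WW	-2.16177
snp_c28_00000	WW	0.909478
snp_c22_00003	WW	-1.91707
snp_c5_00017	WW	0.106404
snp_c3_00010	WW	-2.31885
snp_c21_00002	LYW	5.39193
snp_c1_00017	LYW	1.76828
snp_c4_00011	LYW	3.45615
snp_c6_00000	LYW	0.0469202
snp_c3_00001	LYW	0.25808
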