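context	base_type	mean_h_ppm	sd_h_ppm	mean_n_ppm	sd_n_ppm
WC G-C	G	12.60	0.45	147.30	1.10
WC A-U	U	13.60	0.50	160.80	1.30
GU wobble (G)	G	11.40	0.60	143.00	1.20
GU wobble (U)	U	11.50	0.60	157.50	1.50
sheared G-A	G	10.10	0.50	141.50	1.50
unpaired G	G	10.90	0.70	143.50	2.00
unpaired U	U	11.00	0.80	155.00	2.50
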