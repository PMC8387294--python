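protein	variant_id	chrom	pos	other_allele	effect_allele	cis_trans	iv_r2	beta_exp	se_exp	p_exp	n_exp	beta_cc	se_cc	p_cc	beta_ext	se_ext	p_ext	maf
FHR-1	rs149369377	1	196819479	A	G	cis	0.53	-18.15	1.07	2.6e-43	252	-0.76	0.13	1.9e-9	-0.87	0.02	7.6e-295	0.157
FHR-2	rs4085749	1	196920148	C	T	cis	0.44	-1.55	0.11	6.3e-33	252	-0.78	0.11	2.0e-12	-0.62	0.02	2.2e-184	0.192
FHR-3	rs70620	1	196704997	G	A	cis	0.35	2.02	0.17	1.5e-25	252	-0.06	0.12	0.581	-0.07	0.02	2.7e-3	0.162
FHR-3	rs78606172	20	62087676	G	A	trans	0.16	7.61	1.10	3.9e-11	252	-0.20	0.56	0.721	0.14	0.11	0.210	0.010
FHR-3	rs111260777	11	127117796	T	C	trans	0.14	4.36	0.69	1.5e-9	252	-0.04	0.47	0.924	-0.01	0.07	0.865	0.018
FHR-3	rs113721756	10	116647277	C	T	trans	0.12	4.92	0.84	1.7e-8	252	-0.76	0.54	0.161	0.12	0.09	0.187	0.012
FHR-3	rs11711512	19	56030803	G	A	trans	0.12	4.57	0.79	2.5e-8	252	0.75	0.45	0.096	0.09	0.10	0.351	0.016
FHR-3	rs117468955	12	92269900	A	G	trans	0.12	4.72	0.82	3.0e-8	252	0.06	0.53	0.913	-0.03	0.10	0.789	0.015
FHR-3	rs4790395	17	2852632	C	T	trans	0.11	-6.50	1.14	3.6e-8	252	-0.04	0.78	0.955	0.16	0.13	0.206	0.031
FHR-4	rs12047098	1	196835106	T	C	cis	0.25	-1.75	0.19	1.1e-17	252	-0.86	0.12	8.9e-14	-0.67	0.02	5.5e-198	0.172
FHR-5	rs72732232	1	196265545	T	A	cis	0.15	-0.52	0.08	2.2e-10	252	-1.56	0.32	1.4e-6	-0.86	0.07	3.2e-41	0.026
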