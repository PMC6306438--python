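snp	locus	chr	bp	effect_allele	other_allele	eaf	beta_crp	se_crp	p_crp	beta_t2dm	se_t2dm	p_t2dm
rs6700896	LEPR	1	65862370	T	C	0.38	-0.147	0.01429	1.6E-21	-0.00995	0.01493	0.41
rs4537545	IL6R	1	152685503	T	C	0.43	-0.108	0.01531	5.1E-11	-0.01980	0.00991	0.21
rs7553007	CRP	1	157965173	A	G	0.33	-0.207	0.01429	3.3E-38	-0.01980	0.01479	0.14
rs1183910	HNF1A	12	119905190	T	C	0.32	-0.136	0.01429	1.2E-17	0.02956	0.00981	0.059
rs4420638	APOE	19	50114786	G	A	0.19	-0.218	0.01837	2.1E-25	-0.11333	0.02228	2.0E-7
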