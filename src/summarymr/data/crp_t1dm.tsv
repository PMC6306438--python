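snp	chr	bp	effect_allele	other_allele	eaf	beta_crp	se_crp	p_crp	beta_t1dm	se_t1dm	p_t1dm
rs6700896	1	65862370	T	C	0.38	-0.147	0.01429	1.6E-21	-0.029	0.026	0.2646856
rs7553007	1	157965173	A	G	0.33	-0.207	0.01429	3.3E-38	0.037	0.026	0.1547139
rs1183910	12	119905190	T	C	0.32	-0.136	0.01429	1.2E-17	-0.037	0.027	0.17057
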