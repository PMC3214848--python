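# Ten-gene autism susceptibility SNP panel with risk-allele frequencies
# (exploratory-sample estimates). The risk allele is the allele associated
# with the disease; other_allele entries are conventional placeholders where
# the reference study did not print the second allele.
snp_id	gene	risk_allele	other_allele	risk_freq
rs12410279	MARK1	A	G	0.85
rs2292813	SLC25A12	C	T	0.90
rs2278556	ATP2B2	A	G	0.40
rs6872664	PITX1	C	T	0.89
rs2235076	GRIK2	G	A	0.98
rs10951154	HOXA1	T	C	0.86
rs7794745	CNTNAP2	T	A	0.40
rs1861972	EN2	A	G	0.73
rs5918	ITGB3	T	C	0.87
rs7766973	JARID2	C	A	0.60
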