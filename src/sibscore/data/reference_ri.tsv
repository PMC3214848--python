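# Published reproducibility indexes (all children / male / female cases)
# for the ten-marker panel, as reported in the original sex-specific
# genetic-score study on the exploratory family sample.
snp_id	gene	ri_all	ri_male	ri_female
rs12410279	MARK1	0.93	0.468	1.00
rs2292813	SLC25A12	0.52	0.757	0.52
rs2278556	ATP2B2	0.99	0.997	0.59
rs6872664	PITX1	0.97	0.983	0.30
rs2235076	GRIK2	0.36	0.277	0.59
rs10951154	HOXA1	0.93	0.958	0.20
rs7794745	CNTNAP2	1.000	1.000	0.89
rs1861972	EN2	0.97	0.880	0.94
rs5918	ITGB3	0.98	0.646	1.00
rs7766973	JARID2	0.98	0.951	0.88
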