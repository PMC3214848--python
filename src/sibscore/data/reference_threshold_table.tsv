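# Published genetic-score sensitivity/specificity columns by sex
# (exploratory sample) from the original sex-specific genetic-score study.
# Rule: score >= threshold classifies high risk.
sex	threshold	sensitivity	specificity
male	3	1.00	0.00
male	4	1.00	0.01
male	5	0.97	0.03
male	6	0.90	0.19
male	7	0.75	0.41
male	8	0.47	0.64
male	9	0.24	0.86
male	10	0.08	0.95
male	11	0.02	0.98
male	12	0.00	1.00
female	4	1.00	0.00
female	5	1.00	0.00
female	6	1.00	0.00
female	7	1.00	0.00
female	8	0.99	0.10
female	9	0.90	0.20
female	10	0.78	0.40
female	11	0.61	0.65
female	12	0.37	0.86
female	13	0.17	0.94
female	14	0.03	0.99
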