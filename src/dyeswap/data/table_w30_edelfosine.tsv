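# Published 3x3 cross-classification: 30 uM wortmannin (vs 1 uM) calls (rows)
# vs edelfosine calls (columns), Arabidopsis suspension cells, Bonferroni p < 0.05.
# row_treatment=W30	col_treatment=edelfosine	printed_n=24539
row_class	col_class	observed	printed_theoretical	printed_ratio
UP	UP	229	21.83	10.5
UP	NC	1059	1251.05	0.88
UP	DOWN	12	27.12	0.44
NC	UP	173	362.87	0.48
NC	NC	21307	20799.18	1.02
NC	DOWN	133	450.95	0.29
DOWN	UP	10	27.30	0.37
DOWN	NC	1249	1564.77	0.8
DOWN	DOWN	367	33.93	10.81
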