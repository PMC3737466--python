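# Published 3x3 cross-classification: n-ButOH (vs tert-ButOH) calls (rows)
# vs edelfosine calls (columns), Arabidopsis suspension cells, Bonferroni p < 0.05.
# row_treatment=n-ButOH	col_treatment=edelfosine	printed_n=23566
row_class	col_class	observed	printed_theoretical	printed_ratio
UP	UP	91	21.59	4.21
UP	NC	1077	1201.68	0.90
UP	DOWN	82	26.73	3.06
NC	UP	277	364.00	0.76
NC	NC	20531	20261.26	1.01
NC	DOWN	268	450.75	0.59
DOWN	UP	39	21.42	1.86
DOWN	NC	1047	1192.06	0.88
DOWN	DOWN	154	26.52	5.81
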