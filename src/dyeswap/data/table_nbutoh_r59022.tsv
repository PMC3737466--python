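# Published 3x3 cross-classification: n-ButOH (vs tert-ButOH) calls (rows)
# vs R59022 calls (columns), Arabidopsis suspension cells, Bonferroni p < 0.05.
# row_treatment=n-ButOH	col_treatment=R59022	printed_n=24194
row_class	col_class	observed	printed_theoretical	printed_ratio
UP	UP	37	9.53	3.88
UP	NC	1248	1286.18	0.97
UP	DOWN	17	6.30	2.70
NC	UP	122	158.32	0.77
NC	NC	21458	21378.02	1.14
NC	DOWN	61	104.65	0.58
DOWN	UP	18	9.15	1.97
DOWN	NC	1194	1235.80	0.97
DOWN	DOWN	39	6.05	6.45
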