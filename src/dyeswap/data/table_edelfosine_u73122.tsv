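# Published 3x3 cross-classification: edelfosine calls (rows) vs U73122 calls (columns),
# Arabidopsis suspension cells, Bonferroni p < 0.05. Known to be internally
# inconsistent as printed (row totals and some cells do not match the observed counts).
# row_treatment=edelfosine	col_treatment=U73122	printed_n=21369
row_class	col_class	observed	printed_theoretical	printed_ratio
UP	UP	127	12.93	9.90
UP	NC	240	355	0.54
UP	DOWN	0	10.33	0
NC	UP	600	702	0.85
NC	NC	19466	19265	1.02
NC	DOWN	462	561	0.82
DOWN	UP	3	15.9	0.19
DOWN	NC	340	436.4	0.51
DOWN	DOWN	122	12.71	16.53
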