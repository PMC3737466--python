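# dyeswap

Two-color spotted microarray analysis for pharmacological transcriptomics:
dye-swap differential expression, cross-treatment contingency enrichment,
transcriptome signature ranking, and promoter motif over-representation —
with a synthetic-data generator that reproduces the statistical structure
of the real experiments so the whole chain can be exercised and validated
without any external download.

## The scientific problem

Inhibitor screens on *Arabidopsis thaliana* suspension cells ask whether a
basal signaling pathway (here phosphoinositide-specific phospholipase C
coupled to diacylglycerol kinase) controls gene expression. Each treatment
(edelfosine, U73122, 30 µM wortmannin, R59022, *n*-ButOH) is compared to
its control on two-color spotted arrays, giving per-probe regulation calls
UP / NC / DOWN. The question "do two inhibitors act on the same pathway?"
becomes: are the regulation calls of two treatments statistically
dependent, far beyond what independent action would produce? Downstream,
the promoters of co-regulated genes are scanned for over-represented
cis-elements (e.g. the CRT/DRE core `CCGAC` bound by DREB2 transcription
factors), and the treatment signature is ranked against an expression
compendium to identify which stresses it resembles.

## Methods at a glance

**Differential expression.** Per array, spots flagged as badly formed are
excluded; the intensity-dependent dye bias is removed by a loess fit of
M = log2(ch1/ch2) on A = ½·log2(ch1·ch2); print-tip effects are removed by
per-block median centering. Dye-swap technical replicates are averaged
(sign-flipping the reversed orientation) to one M per probe and biological
replicate. A probe's statistic is

    t_g = M̄_g / sqrt(s²_trim · w_g / n)

where s²_trim is the pooled mean of per-probe variances inside the
[2.5%, 97.5%] empirical quantile band (rescaled by the chi-squared
truncation factor so it stays unbiased), w_g downweights probes missing a
dye-swap member, and p-values from the standard normal reference are
Bonferroni-adjusted over the probes tested. Calls use adjusted p < 0.05.

**Cross-treatment enrichment.** Calls of two treatments are crossed on
their common signal probes into a 3×3 table; theoretical counts under
independence are rowᵢ·colⱼ/N, each cell's enrichment ratio is
observed/theoretical, and independence is tested by Pearson's chi-squared
(df 4). Three treatments are compared against mutual independence
(expected = N·p₁p₂p₃ per joint cell). Venn region counts and
hypergeometric set overlaps cover gene-list comparisons.

**Signature ranking.** The K = 200 most up- and 200 most down-regulated
probes with their mean log-ratios form a signature; every compendium
experiment is scored by Pearson correlation over the signature genes and
ranked.

**Motif over-representation.** Promoters (≤1000 bp upstream, truncated at
neighboring genes, 5'UTR excluded) are scanned exhaustively for all 4–10 bp
words present in the foreground; each word (identified with its reverse
complement) is tested foreground-vs-background by presence/absence
chi-squared at p < 10⁻⁵, significant words are clustered by greedy
single-linkage ungapped alignment into IUPAC consensus modules and matched
against a small catalogue of plant cis-elements.

## Worked example

A full synthetic run — two dependent treatments, four hybridizations per
comparison, a planted `CCGAC` motif and a 50-experiment compendium with
planted correlated columns:

```bash
dyeswap run --out-dir demo --seed 1
```

The cross-classification of the two treatments' calls
(`demo/contingency_edelfosine_vs_w30.txt`):

```
Observed (Theoretical) ratio  w30 > control  w30 <> control  w30 < control  Total
edelfosine > control          13             36              0              49
                              (1.32)         (46.60)         (1.08)
                              9.82           0.77            0
edelfosine <> control         39             1833            30             1902
                              (51.38)        (1808.76)       (41.86)
                              0.76           1.01            0.72
edelfosine < control          2              32              14             48
                              (1.30)         (45.65)         (1.06)
                              1.54           0.70            13.3
Total                         54             1901            44             1999
chi-squared = 276.2, df = 4, p = < 2.2e-16
```

Reading: of 1999 probes with signal in both comparisons, 13 are induced by
both treatments where independence predicts 1.32 — a 9.8-fold enrichment —
and the joint chi-squared rejects independence outright, exactly the
pattern expected when the two inhibitors hit one pathway (the generator
planted 80% shared regulated genes). The run report further shows the
planted promoter motif recovered as one cluster with consensus `CCGACTA`,
and the five planted compendium experiments occupying the top signature
ranks (r ≈ 0.82–0.84 against noise columns at ≈ 0).

The published contingency tables shipped with the package can be
recomputed from their observed counts and diffed against the printed
values:

```bash
dyeswap reference-tables
```

which reports, e.g., `w30_edelfosine: chi2=5685 df=4 p=< 2.2e-16` with the
theoretical cell for (W30 up, edelfosine up) at 21.83 and the enrichment
ratio rendered 10.5, and honestly flags the cells of the one table that is
internally inconsistent as printed.

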