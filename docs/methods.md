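# Methods

This note records the models, estimators and numerical choices behind the
package, what the synthetic generator does and does not emulate, and the
known limitations.

## Synthetic two-color experiments

Each treatment-vs-control comparison is simulated at spot level for
`n_bio_reps` biological replicates (default 2), each hybridized in both
dye orientations (default on), i.e. four hybridizations per comparison
with the defaults. Per spot,

    A = A_gene + jitter,           A_gene ~ Normal(a_mean=10, a_sd=1.5)
    M = s·effect + bias(A) + block_offset + Normal(0, noise_sd)
    ch1 = 2^(A + M/2),  ch2 = 2^(A − M/2)

with `s = +1` on forward and `−1` on dye-swapped arrays. Defaults: spot
noise 0.3 (log2), dye-bias curve quadratic in A with coefficients
(0.4, −0.15, 0.08) — the banana-shaped M–A artifact loess is designed to
remove — per-array block offsets drawn Normal(0, 0.2) unless fixed in the
config, and 1% of spots flagged invalid ("badly formed"). Base abundance
is log-normal on the A scale; the choice is conventional, as intensity
distributions are rarely reported for spotted arrays.

Regulated genes (default 5% per treatment) get a signed log2 effect with
magnitude |Normal(effect, 0.25·effect)| (default effect 1.5). Dependence
between treatments is a single dial: a fraction `frac_shared` of each
treatment's regulated genes is drawn from one latent "pathway" set whose
members carry a fixed sign, so at `frac_shared = 0` treatments regulate
independently sampled genes, and at 1 they regulate the identical set in
the identical direction. This is the structure the cross-classification
stage is meant to detect.

What the generator does *not* emulate: probe cross-hybridization, spatial
scratch artifacts, pooling of RNA preparations within a biological
replicate (absorbed into spot noise), correlated biological variation
between replicates, and heteroscedastic intensity-dependent noise. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to every artifact of real scanners.

Promoter sets are i.i.d. sequences with AT-rich plant-like composition
(A/T 0.32, C/G 0.18); planted motifs are substituted once per selected
sequence at a uniform position and strand. Compendium experiments are
either planted (truth effect vector + Normal(0, 0.5) noise) or null
(independently permuted effect vector + noise), so all columns share one
marginal distribution and only planted columns correlate with the truth.

All randomness flows from one seed through `numpy` `SeedSequence` spawns
(one stream per array), so outputs are byte-identical across runs.

## Normalization

Per array: spots flagged invalid or with a non-positive channel are
dropped; `M = log2(ch1/ch2)` is corrected by subtracting a loess fit of M
on A (statsmodels `lowess`, degree 1, 3 robustness iterations, span 0.2);
each print-tip block's median M is then subtracted exactly. No background
subtraction and no between-array normalization are applied.

Span 0.2 was chosen because degree-1 loess at span 0.3 visibly undertracks
curvature (a noise-free M = 0.5·sin(A) benchmark retains residuals up to
0.09 at span 0.3 versus 0.04 at 0.2), while 0.2 still averages ≈400 spots
per window on a realistic array. The loess smoother is not a projection:
re-normalizing already-normalized data moves values by a small but nonzero
amount (≈1e-2 with noise, ≈8e-3 even noise-free), so only block centering
is exactly idempotent; the tests bound the second-pass movement instead of
asserting exact idempotence.

Dye-swap averaging flips the sign of the swapped member and averages all
available spots per probe and biological replicate; a probe present in
only one member keeps the available value, with the count recorded.

## Differential expression

With two biological replicates the per-probe variance (1 degree of
freedom) is useless on its own, so a pooled trimmed variance is used:
per-probe variances inside the [0.025, 0.975] empirical quantile band are
averaged. Two numerical corrections matter:

1. **Truncation rescaling.** The plain trimmed mean of chi-squared(1)
   variances is biased low by the factor
   (F₃(q₉₇.₅) − F₃(q₂.₅))/0.95 ≈ 0.874, because the discarded upper tail
   carries a disproportionate share of the mass. Without rescaling, the
   null family-wise error rate at Bonferroni 0.05 inflates to ≈0.12; with
   it, measured FWER is ≈0.06 over 400 null experiments.
2. **Precision weights.** A probe that lost one dye-swap member to spot
   filtering has replicate variance ≈1.5× the pooled estimate. Such probes
   are kept (they carry real signal) but their standard error is scaled by
   w_g = mean over replicates of (k_ref/k_g,r). This removes the remaining
   heavy tail of the null t distribution.

The reference distribution is standard normal (the pooled estimate has
thousands of effective degrees of freedom); a Student-t reference with
user-set df is available. Bonferroni adjustment multiplies by the number
of signal probes — probes with at least one valid spot in every biological
replicate, the unit of all counting. A significant probe with mean exactly
zero has no direction and is classified NC.

## Cross-classification

The 3×3 contingency analysis restricts to probes with signal in both
comparisons before anything else. Theoretical counts are the outer product
of the marginals over N; cell ratios are observed/theoretical; the test is
Pearson's chi-squared without continuity correction, df 4. Cells with
theoretical count below 5 only trigger a warning (the published tables
contain none after restriction to signal probes); a zero marginal removes
its cells from the statistic and reduces the degrees of freedom. Ratios
render at two decimals, one decimal from 10 upward, and `0` for an empty
cell — the display convention of the published tables. P-values below
2.2e-16 are additionally rendered as the string `< 2.2e-16`.

The triple-overlap expectation uses marginal class proportions on the
three-way common probe set under mutual independence; which probe set the
original analysis used is not documented, and the three-way common set is
the conservative reading.

The shipped reference tables are recomputed from observed counts alone;
the diff flags printed cells that disagree with their own counts rather
than patching them. One table (edelfosine vs U73122) is internally
inconsistent as printed (its row totals do not match its cells) and is
reproduced structurally only.

## Signature ranking

The signature is the K (default 200) probes with the largest and smallest
mean normalized log-ratios, with those values as the reference vector.
Experiments are ranked by descending Pearson correlation computed over the
signature genes; genes missing from the compendium are dropped with a
warning, and zero-variance experiment columns get an undefined correlation,
a degeneracy flag and the last rank.

## Promoter extraction and motif scan

Promoters span up to 1000 bp upstream of the transcription start — the
upstream edge of an annotated 5'UTR when present, else the gene's 5'-most
coordinate — truncated at the nearest body of any other annotated gene on
either strand and at contig edges; minus-strand promoters are
reverse-complemented. Promoters shorter than 20 bp after truncation are
dropped with a record. GFF coordinates are treated as 1-based inclusive;
internal arithmetic is 0-based half-open.

The scan enumerates every exact 4–10 bp word occurring in at least one
foreground promoter; counting is per-promoter presence/absence (which
makes the 2×2 chi-squared well defined) on both strands, each word
identified with its reverse complement. Significance requires p < 10⁻⁵
(Pearson chi-squared, no continuity correction), enrichment in the
foreground, and a minimum expected cell count of 5 (Cochran's validity
condition). The last condition is essential: a 10-mer seen in two
foreground promoters and no background promoter has a nominal chi-squared
p ≈ 1e-23 that is pure approximation failure, and without the rule
thousands of such words flood the output. Foreground promoters may remain
in the genome-wide background, as in whole-genome reference scans;
exclusion is configurable.

Significant words are clustered by greedy single-linkage: two words link
when their best ungapped alignment (all offsets, both strands, overlap ≥4)
matches at ≥75% of overlapping positions. Each cluster is summarized as a
position-wise IUPAC consensus over members aligned to the longest word,
and matched against an editable catalogue of plant cis-elements by
IUPAC-compatibility score (fraction of compatible positions, ties broken
by overlap length then name, flagged).

## Problem sizes used in validation

The shipped validation uses 2000-probe arrays for recovery and dependence
checks (10 seeds per shared-fraction setting), 300-probe arrays for the
100-experiment null family-wise error study, 100 foreground vs 5000
background 1000-bp promoters for motif recovery (10 seeds), and
40-experiment compendia (10 seeds) for signature recovery — sizes at which
every statistical property under test is already stable while the full
suite stays inexpensive.

## Known limitations

- No between-array normalization, background subtraction, or
  empirical-Bayes variance moderation — deliberately matching the
  original analysis protocol rather than modern best practice.
- Whether the original trimmed-variance procedure pooled variances or
  substituted per-gene trimmed estimates is not documented; the pooled
  interpretation is implemented (configurable trim band).
- Motif discovery is exact-word based; gapped or PWM motifs and
  under-represented (depleted) words are out of scope.
- The cis-element catalogue is a small curated stand-in for full motif
  databases; matches identify the closest shipped pattern only.
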