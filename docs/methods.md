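# Methods

`nregulon` implements, as a tested and reusable pipeline, the analysis that
identifies genes whose translation — not transcription — depends on the
elongation factor eIF5a in effector CD8+ T cells. The measured object is the
*nascent proteome*: proteins synthesized during a short window in which cells
incorporate the methionine analogue AHA, captured by click chemistry and
quantified by label-free LC-MS at the peptide level. Because the pipeline's
defining outputs are cohort definitions and resampling statistics rather than
instrument-specific numbers, it is driven by a synthetic-data generator with
planted, recoverable structure; every stage can therefore be scored against
ground truth.

## Study design emulated by the generator

Four biological groups with four replicates each, plus non-labelled
Background samples:

| group | meaning | input cells (default) |
|---|---|---|
| Mock | vehicle-treated control | 12.5e6 |
| GC7 | deoxyhypusine-synthase inhibitor (blocks eIF5a hypusination) | 32.5e6 |
| WT | CRISPR-untargeted cells sorted from the KO culture | 10e6 |
| KO | *Eif5a* CRISPR knockout, FACS-sorted | 10e6 |
| Background | non-AHA-labelled control for the click capture | 12.5e6 |

KO and WT replicates sharing a `pair_id` come from the same culture, which is
why the KO contrast is a paired test. GC7 cultures are loaded at 2.6x the
Mock cell number: GC7 shuts down global translation roughly threefold per
cell, and the heavier loading equalizes total injected peptide. The
generator plants exactly this structure — a global GC7 per-cell shift of
−log2(3), a loading term `log2(input_cells / min input_cells)`, and targeted
down-shifts (default −1.5 log2) in both KO and GC7 for a set of
translational targets drawn preferentially (odds 3) from PPP/PPG-containing
proteins. mRNA is mostly unchanged; a small fraction of non-target genes
(5%) is transcriptionally down, shifting protein and mRNA together, and must
be rejected by the Venn logic. A disjoint subset (80 genes) is annotated as
5'TOP with a mild positive KO shift of log2(1.29).

Peptide intensities are log-normal: per-peptide log2 intensity = protein
baseline N(17, 2.5) + group effect + loading + peptide offset N(0, 1) +
noise N(0, 0.25). Each protein gets 1 + Poisson(7) peptides, 95% of them
unique. Whole protein/sample cells are blanked missing-at-random at rate
0.03. These three values were chosen together so that the expected
filter-casualty rate (proteins losing the unique-peptide or 3-of-4 rule by
chance) is a few percent — blanks usually leave at least three observed
replicates per group, and planted targets are recoverable in principle.
`annotate_filter_casualties` marks the genes for which that failed, so
recovery metrics can distinguish filter losses from analysis errors.
Background samples sit 3.5 log2 (~11x) below the labelled baseline, except
for a 2% contaminant fraction carrying full signal. RNA counts are negative
binomial (dispersion 0.1, library 1e6) around
`lib_size * rel_expr * 2^rna_log2fc`, Poisson in the dispersion→0 limit.

What the generator deliberately does **not** model: peptide detectability
and abundance-dependent missingness (real label-free data lose low-abundance
proteins preferentially; our blanks are missing-at-random at the protein
level), spectrum-level artefacts, shared-peptide ambiguity beyond a uniform
non-unique fraction, and correlated biological variation between genes.
Passing tests therefore demonstrate correctness of the pipeline's rules and
calibration of its statistics under the stated model — not robustness to
every pathology of real MS data.

## Quantification and filters

Protein abundance is `log2(median intensity of the peptides attributed to
the protein in that sample)` — the median rule is used because it is fully
specified, whereas a true iBAQ would need theoretical peptide counts from an
in-silico digest; the even-count median is the mean of the two central
values. The cascade then applies, in order:

1. **expressed** — more than 2 distinct unique peptides (`min_unique = 3`);
2. **detected** — observed in at least 3 of 4 replicates of *every*
   biological group (`min_present = 3`); Background does not count;
3. **AHA-enriched** — mean *linear* abundance over labelled samples at least
   5x the Background mean ("5x more abundant" is a linear fold); a protein
   never observed in Background passes;
4. **single-blank imputation** — a group with exactly one blank gets the
   arithmetic mean of the other replicates' log2 values; two or more blanks
   stay missing; rows failing detection are never imputed.

Filters only toggle flags; rows are preserved with provenance. Imputation
runs after normalization by default (`impute_stage="post"`), so imputed
values are means of comparable numbers; a `pre` switch exists.

## Normalization

Each sample's linear abundances are transformed with a generalized log,

    h_s(x) = log2( (x·b_s + sqrt((x·b_s)^2 + a^2)) / 2 ),

which behaves like `log2(b_s x)` at high intensity and flattens into a
constant near zero, damping the variance explosion of low intensities. The
per-sample scale `b_s` is fitted so the trimmed mean difference (trim 0.2)
between the transformed column and the reference profile — per-gene median
of the transformed matrix, or a designated sample — is zero; this makes
columns comparable and removes loading differences exactly.

The shared offset `a` is *not* fitted by least squares. Both a trimmed-LS
and a Jacobian-penalized profile-likelihood objective turn out to be nearly
flat in `a` on realistic data (per-sample estimates scattered over an order
of magnitude on one simulated dataset) and systematically biased low
relative to the variance-stabilizing value, which for linear-scale noise
`var = (cv·mean)^2 + s0^2` is `a* ≈ s0·b/cv`. Since the property the
transform exists for is a flat relation between replicate spread and mean,
`a` is chosen to zero the slope of replicate SD on mean (complete-case
genes, SD winsorized at its 95th percentile to resist genuinely shifted
genes). That slope is monotone in `a`, so a bisection finds the root
reliably; when the data are already homoscedastic the fit collapses to plain
`log2`. This is a deliberately simple stand-in for the published
robust-maximum-likelihood vsn fit, with the same testable outcomes
(comparable columns, stabilized variance) and none of its machinery.

The input-cell adjustment subtracts `log2(input_cells(s) / min input_cells)`
— a pure per-column shift onto the per-cell scale of the smallest input.
The minimum (not the mean) is the baseline so corrections are non-negative;
contrasts are unaffected either way. After normalization plus adjustment the
global GC7 effect reappears as roughly the input-cell ratio (−1.38 log2 ≈
2.6x), which is exactly how the per-cell reduction becomes visible in this
design.

Quality control is classical (Torgerson) MDS on Euclidean distances between
sample columns over complete-case genes (1 − Pearson available as an
option); variance fractions are eigenvalues over the sum of positive
eigenvalues.

## Differential testing

* GC7 vs Mock: two-sided equal-variance t test per gene on log2 values (the
  equal-variance form is the plain "t test"; a Welch switch would be easy
  but is not the default), Benjamini–Hochberg FDR across genes.
* KO vs WT: two-sided paired t test on per-culture differences; downstream
  calls use the raw p.
* Zero-variance convention: values identical within and across groups → p =
  1; identical within but different across → p = 0 (limits of the t
  statistic). Genes with fewer than two values per group (or two complete
  pairs) get missing p and leave the BH family.
* RNA (GC7 vs Mock): a simplified negative-binomial likelihood-ratio test —
  total-count library normalization, method-of-moments dispersion from
  pooled within-group variances, tagwise values shrunk toward the common
  mean with weight 0.7 on the common component (`tagwise_weight = 0.3`; with
  four replicates per group the tagwise estimate is noisy, and weaker
  shrinkage leaves the test visibly anticonservative), chi-square(1)
  reference for the LRT, 0.5 pseudo-count for fold changes. The design goal
  is calibration: on a 2000-gene null with dispersion 0.1 the measured
  type-I error at nominal 0.05 stays within 0.05 ± 0.02. With dispersion
  forced to 0 the test reduces exactly to the Poisson LRT, which is the
  independent oracle used in the tests.

## Venn classification

With thresholds `{rna_fdr_hi: 0.1, rna_fdr_lo: 0.01, rna_fc: 2, prot_fdr:
0.05, prot_p: 0.05, prot_fc: 1.5}`:

* `rna_not_reduced` ⇔ RNA FDR > 0.1 **or** (FDR < 0.01 **and** linear fold >
  2) — read as A OR (B AND C): the mRNA is either unchanged or went *up*;
* `gc7_protein_down` ⇔ protein FDR < 0.05 and log2FC < −log2(1.5);
* `ko_protein_down` ⇔ paired p < 0.05 and log2FC < −log2(1.5);
* `translational_gc7` = both of the first two; `eif5a_regulated` adds the
  KO criterion.

Fold thresholds written as "FC < −1.5" are signed linear folds, i.e.
|log2FC| > log2(1.5) ≈ 0.585 in the stated direction. Genes without an RNA
measurement are excluded from translational sets by default
(`missing_rna="exclude"`); a `pass` policy treats them as not reduced.

## Motif statistics and bootstraps

Trimer counts are overlapping (PPPP contains PPP twice) and never span
sequence boundaries; frequencies are per residue (count / total length),
while window counts (len − 2) feed the Fisher tables. For each target motif
(PPP, PPG, DVG, DDG, GGT, RDK) the 2x2 table contrasts the motif's window
count in the gene set against the pooled count of 50 random trimers in the
same set — drawn uniformly from the 8000-trimer alphabet minus the targets
so the null rate is clean — tested with one-sided (greater) Fisher's exact
test; a motif with zero occurrences gets p = 1. Known limitation: for
self-overlapping motifs (PPP is the only target that overlaps itself),
natural runs of proline make the count overdispersed relative to the
hypergeometric null, so on natural sequences the PPP test is mildly
anticonservative (~12% at nominal 5% in simulation). The power tests
therefore use planted insertions, which cannot clump, at 2x (signal) and 1x
(matched null) of the random-trimer rate.

The polyproline bootstrap reports the percentage of a called set contained
in the PPP/PPG reference list against the same statistic for `n_reps = 1000`
random draws of `n_draw = 2900` genes without replacement from the
transcriptome universe, with one-sided (greater) add-one empirical p and
box statistics (median, quartiles, 1.5*IQR whiskers) of the null. For
synthetic runs the reference list is computed from the generated sequences
themselves. Inside `run_all` the draw is additionally capped at 80% of the
universe, because drawing essentially the whole universe without replacement
degenerates the null to a constant — the real transcriptome is an order of
magnitude larger than the draw, synthetic universes need not be.

The 5'TOP shift test takes any annotated gene list: observed statistic =
median linear KO fold change of the list; null = medians of random same-size
gene sets. The empirical p is two-sided by counting null medians at least as
far from the null median as the observed value, with the add-one rule — this
reduces to rank-based one-sided values in the extreme cases and stays exact
under the degenerate list-equals-universe case. A two-tailed t test of the
list's log2FCs against all other tested genes, and one of the observed
median against the null medians, are reported alongside, since either
comparison is defensible; IRES or uORF gene lists reuse the same operation
unchanged.

## Numerical and policy choices

* Empirical bootstrap p-values use the add-one estimator
  `(1 + hits)/(n_reps + 1)`: never zero, uniform under the null.
* BH adjustment delegates to `statsmodels.multipletests`; tests verify it
  against a brute-force step-up implementation to 1e-12.
* Fisher p delegates to `scipy.stats.fisher_exact`; tests verify it against
  integer-exact hypergeometric enumeration on all tables with margins ≤ 20.
* The NB mean MLE with offsets uses vectorized Newton iterations on log μ;
  dispersion 0 short-circuits to the closed-form Poisson solution.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  generator and bootstrap is byte-deterministic given its seed, and
  `run_all` derives per-stage seeds from a single master seed.
* Problem sizes in the test-suite and acceptance runs (3000-gene studies,
  2000-gene calibration nulls, 200-trial KS checks at 200 bootstrap
  replicates) are chosen as the smallest sizes at which the measured
  properties are stable; they mirror the real study's analysis scale
  (~3000 analysed proteins) rather than the full transcriptome.

## Known limitations

* Protein summarization ignores shared-peptide reattribution; non-unique
  peptides only affect the expressed flag.
* The glog fit assumes one common noise floor across samples after
  scale alignment; per-sample additive noise that does not track loading
  would need per-sample offsets, which this stand-in does not fit.
* The NB test's chi-square reference is asymptotic; with four replicates it
  stays within the calibration band only thanks to the strong dispersion
  shrinkage, and would be anticonservative with `tagwise_weight` near 1.
* MDS uses complete-case genes only; with heavy missingness the embedding
  can rest on a biased gene subset.
* The specific-lysis formula `100·(1 − ratio_with_T / ratio_without_T)` is
  the standard ratiometric definition — zero without effectors, approaching
  100 as pulsed targets disappear; the assay itself never states a formula.
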