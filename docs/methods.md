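# Methods

This note documents the statistical models, conventions and design choices
behind `degnet`, in the order the pipeline runs them.

## Synthetic study model

The generator emulates a multi-cohort tumor/normal transcriptome study
plus the perturbation, motif and survival experiments that follow from it.

**Counts.** Gene g in sample j of cohort c is drawn
NB(mean = s_j · μ_g · b_cg · 2^(x_j β_g), variance = μ + α μ²), with

- baseline μ_g ~ log-normal(log-mean 5, log-sd 2 in natural log) — spans
  ~e¹ to ~e⁹ counts, covering realistic depth variation without extremes;
- library factor s_j ~ Uniform(0.5, 2);
- cohort batch jitter b_cg = 2^N(0, 0.2) per gene per cohort (on by
  default; it makes the meta-intersection stage non-trivial because each
  cohort sees shifted baselines);
- dispersion α = 0.1 (standard bulk RNA-seq overdispersion);
- β_g = ±lfc_magnitude (default 2) for the planted DE genes
  (de_fraction = 0.05 of 2000 genes by default, split half up / half down,
  direction-consistent across cohorts), 0 otherwise.

Default cohort sizes are 43+43, 20+20 and 21+21 healthy+tumor samples —
the design of the public-cohort study the pipeline targets. The 2000-gene
universe is a desk-scale choice: large enough for BH adjustment and
dispersion moderation to behave as they would genome-wide, small enough
that the whole chain runs in seconds.

**Hub and knockdown.** One planted up-regulated DE gene acts as the hub
TF with a regulon of 40 DE targets; `generate_tf_prior` adds decoy TFs
(default 10, regulons ≤ 10) drawn from the DE genes so the prior's
restriction to DEGs is non-trivial. The knockdown experiment (default
3 vs 3, mirroring a typical siRNA design) uses the tumor-state baseline
μ_g·2^β; each of the 40 reversal genes gets a planted effect of
−sign(β)·lfc_magnitude and the hub itself is planted at log2FC −3.
Reversal genes are drawn from all planted DE genes, so overlap with the
regulon is incidental — the rescue stage does not presuppose the network.

**Promoters.** I.i.d. uniform A/C/G/T backgrounds of 2000 nt; the PWM
consensus (or its reverse complement for minus-strand plantings) is
written at the planted TSS-relative offsets (−1800, −1250, −400 by
default, one per reporter fragment). Real promoters have GC skew, CpG
islands and repeats; passing recovery tests on uniform background
therefore shows coordinate and scoring correctness, not real-genome
specificity.

**Survival.** Event times are exponential with hazard h₀·HR^z, z = 1 for
samples above the median expression of the designated gene (h₀ = 0.05,
HR default 2). Censoring is independent: with probability `censor_rate` a
record is censored at a Uniform(0, T) fraction of its drawn event time,
so the expected censored fraction equals the configured rate exactly.

All generators derive per-stage substreams from the single global seed
via `SeedSequence(seed, spawn_key=stage)`, so stages are independently
reproducible and identical configs give byte-identical outputs.

What the generator does **not** emulate: gene–gene correlation, GC/length
biases, dispersion–mean trends, cohort-specific sample quality, informative
censoring. Recovery results on synthetic data bound what the methods can
do under their own assumptions; they do not certify performance on any
particular real cohort.

## Normalization and differential expression

Size factors are median-of-ratios: reference genes are those with
positive counts in every sample; s_j = median_g K_gj / geomean(K_g·).
When no gene qualifies, a flagged fallback uses positive-count
pseudo-references. Note the exact invariance: scaling one sample by c
scales factor *ratios* by c (the geometric-mean reference itself moves by
c^{1/n}).

Two test modes cover the two kinds of matrices in circulation (deposited
matrices are often RPKM even when the upstream analysis was count-based):

- **nb_wald** (counts): per-gene method-of-moments dispersion on
  normalized counts, pooled across groups after removing group means
  (α̂ = max(10⁻⁸, (s² − x̄)/x̄²)), then moderated toward the across-genes
  median with a fixed prior weight of 20 residual degrees of freedom:
  α̃ = (d_g·α̂ + 20·median α̂)/(d_g + 20). The Wald statistic
  log2FC/SE (delta-method SE with pseudocount 0.5) is referred to the
  normal distribution. The moderation is the minimal stabilization that
  makes the normal reference honest at small n: with raw per-gene MoM
  dispersions the plug-in SE is noisy enough that the null rejection rate
  at 10 vs 10 is ≈ 0.064 instead of 0.05, while a t(n−2) reference
  over-corrects so severely at 3 vs 3 that two-fold changes can never
  reach BH-adjusted significance. With moderation the measured null rate
  is ≈ 0.056 at 10 vs 10 and 3-vs-3 contrasts retain power. The weight 20
  is a fixed method constant of the order of limma's typical fitted prior
  df; it is not estimated from the data. No empirical-Bayes trend, LFC
  shrinkage, independent filtering or outlier handling is performed —
  exact parity with any specific DESeq2 configuration is a non-goal.
- **welch_log** (continuous, e.g. RPKM): Welch t on log2(x + 1) with a
  variance floor of 10⁻⁸ per group (flags complete separation without
  0/0); log2FC is the difference of group means of log2(x + 1). Counts
  passed to this mode are size-factor normalized before the transform.

Genes with zero variance and equal group means get p = 1 and log2FC = 0.
DEG calling uses strict inequalities, |log2FC| > 0.5 and BH p-adj < 0.05.

Calibration contract: on 50 null replicates (2000 genes, 10 vs 10) the
pooled rejection rate at p < 0.05 must lie within the 95% binomial band
of a single replicate, 0.05 ± 1.96·√(0.05·0.95/2000) ≈ ±0.0096 — i.e.
any miscalibration must be smaller than one dataset's sampling noise.
Both modes meet it (measured ≈ 0.056 and ≈ 0.047).

PCA operates on log2(x + 1) of the top-variance genes (default 2000),
gene-centered, no unit-variance scaling, via SVD.

## Meta-intersection

Per-cohort contrasts run on the shared gene universe (genes missing from
any cohort are dropped — common sets are undefined otherwise). The pooled
contrast concatenates all samples; in nb_wald mode a multiplicative
cohort effect is removed by rescaling each gene's normalized counts by
grand-mean/cohort-mean (exact for balanced cohorts; a full GLM with
cohort covariates is deliberately out of scope), welch_log pools raw
values (documented limitation). A gene is a *common* DEG when called with
the same sign in the pooled contrast and in at least k per-cohort
contrasts; k defaults to all cohorts, the literal reading of
"consistently dysregulated across all datasets". The report carries the
Venn counts (single-only / pooled-only / common, per direction).

## Network, rescue and enrichment

The TF network keeps a prior edge when the TF is in the TF universe and
both endpoints are common DEGs (a flag relaxes the TF-side DEG
requirement); node directions come from the sets that admitted them and
isolated nodes are dropped. TFs rank by out-degree, ties broken
lexicographically; the top entry is the hub.

Rescue classification requires both contrasts significant at the DEG
thresholds with opposite-sign effects; the two classes
(tumor-up-rescued / tumor-down-rescued) are mutually exclusive by
construction and swap under contrast exchange. ORA is the upper-tail
hypergeometric P(X ≥ k) with the universe defaulting to the genes tested
in the relevant contrast (expressed-gene background, not the genome),
BH-adjusted across terms. The rescue network connects each rescue gene to
every enriched term containing it; a term's color is the majority rescue
class among its connected genes, ties labeled mixed.

## Motif scanning and mutant design

Coordinates are TSS-relative, half-open: a promoter of length L occupies
[−L, 0) with the last base at −1; the printed closed fragment ranges map
to [−2000, −1500), [−1500, −1000), [−1000, 0) so the three reporter
fragments tile without double-counting.

PFM → PWM uses column probabilities (count + 0.25)/(total + 1) over a
uniform background, log2 odds; rel_score rescales a window's score into
[0, 1] between the matrix's achievable minimum and maximum (invariant to
per-column constant shifts). Scanning is both-strand by default; windows
containing N are skipped rather than penalized (any N score would be
arbitrary); overlapping opposite-strand sites are both reported with
forward-axis coordinates. The default threshold 0.85 is a common
motif-scan setting; with the bundled consensus-count matrix a 7-of-8
match also clears it, so sporadic near-consensus background hits are
expected (~1.5 per random 2-kb window) — planted occurrences are
distinguished by a perfect rel_score of 1. The bundled PFM is a synthetic
stand-in built from the palindromic C/EBP consensus TTGCGCAA (100 counts
per consensus base); supply a curated matrix for production scans. An
exact background hit probability is available by dynamic programming over
the discretized column score distributions.

Mutant design substitutes, per site, the n highest-information-content
columns (n = 3 by default) to the column's minimum-log-odds base, written
back as forward-strand bases for minus-strand sites; columns are added
until the rescanned site drops below threshold, and a PWM for which even
all-column substitution cannot achieve that is rejected as degenerate.
Because substitutions can create a fresh match overlapping the mutated
window (notably on the opposite strand of a palindromic motif), the
designer rescans and ablates such residual matches iteratively until no
above-threshold site overlaps any substituted position. The substitution
list is reported against the original sequence, one entry per changed
position.

## Survival

Median split assigns samples with expression strictly above the median to
"high" (ties to "low"; the midpoint convention for even n). The
Kaplan–Meier estimator and two-group log-rank test follow the standard
conventions: at tied times events precede censorings, the log-rank
variance is the hypergeometric ΣV with the (n−d)/(n−1) correction, and
the statistic U²/V is referred to χ²(1). A zero-variance configuration
(every event time exhausts one stratum) is an error with a diagnostic
rather than a silent 0/0. Cox regression is intentionally out of scope.

## Known limitations

- nb_wald is a two-group test; multi-factor designs (beyond the
  mean-ratio cohort centering) are unsupported.
- welch_log's pooled meta contrast ignores cohort structure.
- Scan scores carry no p-value calibration (no TFM-style conversion);
  ranking is by rel_score only.
- The rescue hub TF itself, being planted down in the knockdown and up in
  tumors, legitimately classifies as a rescue gene; recovery metrics that
  score only the planted reversal set count it against precision.
- The pipeline is single-threaded by contract; determinism is guaranteed
  only at `--threads 1` semantics.
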