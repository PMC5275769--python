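# Methods

## Study design being emulated

Two small two-class cohorts of oral epithelium samples: a small-RNA-seq
cohort (default 20 tumor vs 7 normal; non-negative integer read counts
over ~400 mature miRNAs) and an RT-qPCR panel cohort (default 20 tumor vs
17 normal; Ct values, lower = more abundant, with a detection ceiling).
The pipeline starts at the count/Ct matrix; read-level processing is out
of scope.

## Synthetic-data generator

**Counts.** Per-miRNA baseline means are log-normal, `exp(N(log 200, 2²))`,
spanning roughly four orders of magnitude as in real small-RNA libraries.
Counts are gamma-Poisson (negative binomial): the default dispersion 0.16
corresponds to a biological coefficient of variation of 0.4, the standard
rule-of-thumb for human bulk samples.  Per-sample library sizes vary
log-uniformly with a 3× max/min spread (no value is reported for brush
libraries; 3× is a typical depth spread after pooling).  Independent
Bernoulli dropout with probability `zero_inflation` (default 0.1) zeroes
observations to emulate structural non-detection; cohorts tolerate up to
60% zeros per miRNA downstream.

**Planted effects.** `n_de` miRNAs (default 15) receive a multiplicative
tumor/normal fold change (default 4), direction randomized 50/50, applied
to the tumor mean before noise, so the population mean ratio equals the
fold exactly.  Effects are planted only on miRNAs above a quantifiability
floor (baseline mean ≥ 50 reads, or ≥4 cycles clear of the Ct ceiling): a
diagnostic signature is by construction measurable, and planting a fold
change below the shot-noise floor would model nothing the pipeline could
meaningfully see.

**Contamination markers.** miR-451a, miR-144-3p and miR-144-5p are
multiplied by `rbc_spike` (default 4) in tumor samples only, emulating the
blood contamination that tumor biopsies show more often.  They are never
part of the differential ground truth; the real names are used so the
default exclusion list matches.

**Ct platform.** True log2 abundance `a ~ N(8, 3²)` maps to
`Ct = 36 − a + N(0, 0.5²)` (0.5 cycles of technical noise); a planted fold
*f* appears as a −log2 *f* cycle shift.  Values above `ct_ceiling`
(default 40) are recorded as undetected.

**Annotation.** A 2000-gene universe; each miRNA targets ~100 uniform
genes plus a 150-gene "promiscuous pool" sampled at probability 0.5 per
gene, emulating the cancer/cell-cycle over-weighting of curated target
databases.  Three promiscuous pathways are drawn from the pool (they reach
significance for any miRNA set); the planted pathway is drawn uniformly
(so with enrichment off it is exchangeable with the background pathways),
and its genes are spread roughly evenly across the planted miRNAs, so the
full signature covers the pathway while no single miRNA comes close —
only the query, not a random set that happens to contain one planted
miRNA, can reach the 10⁻⁶ cutoff.

**What the generator does not model:** batch effects, isomiRs/arm
switching, paired designs, correlated miRNA co-regulation, or
abundance-dependent dropout.  Passing tests therefore show the pipeline's
operating characteristics under a clean two-class model, not performance
on any real cohort.

## Normalization

Housekeeping panel = the `panel_size` miRNAs detected in every sample with
the lowest variance of log expression (ties broken by identifier);
platform defaults 50 (counts) and 40 (ct).  With uniform dropout and small
cohorts the number of universally detected miRNAs can fall below the
platform default, so the convenience driver caps the panel at what the
cohort supports.  The per-sample factor is the **median** over the panel of
value ratios (counts) or Ct differences (ct) against the reference sample
— the median is robust to a few genuinely differential panel members; the
mean is available as an option.  The default reference is the sample with
the most detected miRNAs.  Counts are reported as `log2(x/factor + 1)`;
the +1 pseudocount keeps zeros finite (set it to 0 for exact scale
equivariance on strictly positive data).  Ct values are reported as
`−(Ct − shift)` so that larger always means more abundant.

## Differential expression

Zeros on the counts platform are treated as non-detections (the same
convention as the detection filter), so each miRNA is tested on its
detected values only; miRNAs with fewer than two detected values in a
class are reported as untestable (NaN) and excluded from the BH
adjustment.  The t-test uses pooled variance by default (Welch by flag);
two-sided p-values; BH step-up FDR.  Fold change is `2^Δ` of class means
of log2 values.  The rank product uses the two-sided scheme: separate
up/down statistics over all tumor×normal pairwise rankings, the better
direction reported with a Bonferroni ×2, and `(1 + hits)/(n_perm + 1)`
smoothing so permutation p-values are never zero (default 1000
permutations).  Rank products require complete values; on the ct platform
restrict to complete rows or impute first.  Note that ranking pairwise
log-ratios is invariant to per-sample shifts on the log scale (per-sample
rescaling of linear expression) but not to arbitrary monotone
transformations.

## Classification

Feature selection: miRNAs with training t-test p < α, weights = t
statistics; if none pass, the single smallest-p miRNA (every model has at
least one feature).  α is chosen per outer fold from the grid
{0.05, 0.01, 0.005, 0.001, 0.0005, 0.0001} by inner leave-one-out
accuracy on the n−1 training samples, ties toward the smaller α.  Inner
splits that would leave a class empty are skipped; if no informative inner
split exists, the most inclusive threshold is used.

Algorithm details: CCP threshold = midpoint of the class means of the
compound covariate; BCCP fits per-class Gaussians to the covariate with
equal priors by default; DLDA uses per-feature pooled within-class
variance (floored at 10⁻¹²); kNN is Euclidean with k ∈ {1, 3} (even k
disallowed); the SVM is linear with cost fixed at 1 (the one algorithm
delegated to scikit-learn).  All continuous ROC scores are oriented so
larger = more tumor-like: the signed margin for CCP/DLDA/NC/SVM, posterior
− ½ for BCCP, vote fraction − ½ for kNN; ties in class assignment break
toward "normal" deterministically.  Count zeros are masked and missing
values mean-imputed per feature *within the training fold only*, so
imputation cannot leak the held-out sample.  AUC is the trapezoidal area,
equal to the normalized Mann–Whitney concordance count.

On permuted labels, nested LOOCV accuracy centers slightly **below**
chance (~0.40–0.48 here): with a balanced cohort the held-out sample's
class is always the training minority, and with strongly clustered data a
nearly class-balanced labeling of each cluster makes the within-cluster
majority vote run against the held-out sample.  This anti-conservative
bias is a documented property of leave-one-out with embedded selection,
not an implementation artifact (on i.i.d. features the same code is
unbiased); it is why permutation nulls, not a nominal 50%, should be used
when judging a reported accuracy.

## Pathway enrichment and the negative-control filter

Enrichment p = upper-tail hypergeometric `P(X ≥ k)` for overlap *k*
between the signature's union target set and each pathway, all intersected
with the gene universe (default: union of all pathway and target genes) —
identical to Fisher's one-sided exact test.  The negative-control filter
draws `n_sets` (default 20) random sets of `set_size` (default 11) miRNAs
from the miRNA universe, without replacement within a draw; "appearing in
a negative control" means reaching the same `p_cutoff` (default 10⁻⁶) in
at least one null run (a different hit threshold is exposed).  Query
miRNAs are drawable by default; a flag excludes them.  Because the draws
consume one seeded stream, increasing `n_sets` can only shrink the
retained set.  No multiplicity correction is applied across pathways
beyond the fixed cutoff.

## Problem sizes and determinism

Simulated cohorts default to the study sizes (20+7 counts, 20+17 Ct, 400
miRNAs); tests and the acceptance script use 10+10 cohorts and 10–40
seed replicates, sizes at which every reported property is stable.  All
randomness flows through explicit integer seeds: identical seed and
configuration give bit-identical matrices, GMT files, and filter reports.
The `cohort_seed` argument redraws sampling noise while keeping the
population (baselines and planted effects) fixed — the external-validation
scenario.

## Known limitations

The 13- and 46-miRNA lists and the cohort accuracies of the motivating
study are not reproducible here because the underlying patient data are
not deposited; the pipeline instead demonstrates the method's operating
characteristics on synthetic data with known truth.  The hypergeometric
universe and the miRNA universe for null draws are user choices that
materially affect enrichment p-values.  Rank products and classifiers
assume exchangeable samples (no batch or pairing structure).
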