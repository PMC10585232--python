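# Methods

## The analysis in one paragraph

The pipeline treats a tumour cohort profiled on two molecular levels.
Allele-specific segmented copy-number profiles (total and minor-allele
copies per segment, plus a genome-wide ploidy) are called into gains,
losses, amplification classes and LOH *relative to ploidy*, summarised as
genome-burden percentages, and mapped onto genes. Log2 expression over the
same tumours is clustered into two subtypes by consensus NMF and named by
immune activity. The two levels are then integrated gene by gene: a gene is
*concurrent* when its copy-number state and its expression move together
under pre-registered thresholds. Survival enters through Cox proportional
hazards and Kaplan–Meier estimation over subtype and burden strata, with
five-year administrative censoring of disease-specific survival.

## Copy-number model

**Segmentation.** `pcf_segment` fits an exact least-squares
piecewise-constant signal: it minimises `Σ residual² + γ · #breakpoints`
globally by an O(n²) dynamic program. γ (default 40 in variance-normalised
probe units) trades breakpoints against fit; the suite validates the
optimum against exhaustive enumeration of all segmentations up to length
12. In the synthetic workflow profiles are generated already segmented, so
this operation is exercised by its oracle tests and available for probe
signals.

**Calling.** All calls are relative to the sample's ploidy: gain at
`total ≥ ploidy + 1`, loss at `total ≤ ploidy − 1` (margins configurable;
log-ratio fallback ±0.15 for profiles without integer copies),
amplification / high-level amplification at ≥ 5 / ≥ 10 copies over ploidy,
homozygous deletion at 0 copies, LOH at minor allele 0 with ≥ 1 total
copy. Ploidy-relative calling makes triploid genomes comparable to diploid
ones. The interchange segment format carries no ploidy column; when no
per-sample ploidy is supplied it is inferred as the length-weighted median
total copy number, rounded (the neutral state dominates any usable
profile).

**Burden.** Each call class is summarised as a percentage of the *covered*
genome (uncovered regions do not enter the denominator). Total CNA uses
the union of gain and loss. The disproportionate-LOH rule flags samples
with `pct_loh ≥ 24` and `pct_loss < 6` — tumours whose genomes are
dominated by copy-neutral LOH rather than physical loss.

**Gene mapping.** Default rule: segment-length-weighted mean of total
copies over the gene body (a majority-overlap alternative sits behind
`rule="majority"`); the discrete call is re-derived from the continuous
value. Genes without an overlapping segment are missing and excluded
downstream.

## Subtype discovery

Genes with log2 variance strictly above 0.3 across tumours enter a
consensus NMF: the matrix is shifted by its global minimum (NMF needs
non-negativity), factorised at rank 2 with multiplicative updates
(Frobenius loss) over 50 restarts, each restart on a random 80% gene
subsample with a fresh initialisation. Per-restart sample labels (argmax
mixture coefficient) accumulate into a consensus matrix; the final
partition is an average-linkage cut of `1 − consensus`, and the cophenetic
correlation of that dendrogram measures stability. Rank is fixed at 2 by
default; cophenetic-vs-rank diagnostics can be computed but are not
auto-applied. Naming is functional, not positional: the cluster with the
lower mean immune single-sample score is `immune_deficient` (exact ties
break to the smaller cluster id with a warning). PCA uses gene-centred
SVD with each component oriented so its largest-magnitude loading is
positive; group separation along components is tested by rank-sum.

## Enrichment

*Differential expression* is the Wilcoxon rank-sum test per gene (exact
null when the smaller group has ≤ 8 samples and no ties; tie-corrected
normal approximation with continuity correction otherwise), effect size
the difference of group medians, BH adjustment across genes.

*Competitive gene-set testing* compares the set's mean gene-level z-score
(signed, from the tie-corrected rank-sum statistic) with the non-set mean
by a pooled-variance t statistic whose set term is inflated by
`VIF = 1 + (m−1)·ρ̄`; ρ̄ is the mean pairwise Pearson correlation of the
set genes' within-group residuals, floored at 0. With ρ̄ = 0 this is
exactly the equal-variance two-sample t test. The gene-level statistic is
a rank-sum z-score rather than a moderated t — empirical-Bayes moderation
is deliberately out of scope, and the calibration suite shows type-I error
≤ 0.06 at nominal 0.05 under a correlation-matched null.

*Single-sample enrichment* follows the GSVA recipe for array-like data:
per-gene Gaussian-kernel CDF across samples (bandwidth sd/4), per-sample
ranking of genes by that statistic, symmetric rank weights
`|p/2 − rank|^τ` with τ = 1, and a weighted KS-like random walk whose
score is the maximum positive plus the maximum negative deviation (signed
sum). Scores are exactly invariant to a global expression shift; shifting
a *single* sample's column perturbs its kernel-CDF ranking only through
discrete swaps of near-tied genes, so scores move slightly — the suite
bounds that drift rather than asserting exact invariance.

## Concurrency integration

Per variable gene (variance > 0.3) and direction, tumours with gain
(respectively loss) are compared against copy-neutral tumours: at least 5
aberrant samples, rank-sum FDR < 0.05, median log2 difference beyond ±0.5
in the concordant direction, and Spearman ρ > 0 at FDR < 0.05 between
expression and *ploidy-relative* continuous copy number (`CN / ploidy`;
segmentation estimates are relative to the genome-wide level, and absolute
copies would dilute the dosage signal in ploidy-mixed cohorts). Both FDR
families are BH across all evaluated gene–direction pairs jointly — the
more conservative of the two plausible conventions. Genes without neutral
samples are skipped with a recorded reason.

Gene-set concurrency enrichment compares each set's concurrent proportion
`k/m` with the median proportion across sets via a one-sided Fisher test
on `[[k, m−k], [k_med, m−k_med]]`, `k_med = round(median_prop · m)` — an
explicit operationalisation of "more concurrent genes than the median";
sets are flagged at p < 0.01. Candidate intersection takes subtype-up
genes ∩ gain+up concurrent genes ∩ genes gained in strictly more than 20%
of tumours. Loss/LOH target nomination works inside the deficient subtype
split into high/low loss+LOH burden strata: nominated genes have an
aberration (loss OR LOH, matching "loss and/or LOH") frequency difference
strictly above 0.40, sit on the cancer-critical input list and passed
loss_down concurrency; a per-gene Cox contrast (neutral vs aberrant) and a
high-vs-low-stratum differential expression are attached for reporting.

## Clinical statistics

`fisher_exact_2x2` reproduces the R `fisher.test` conventions: the
two-sided p sums central-hypergeometric probabilities not exceeding the
observed table's; the odds ratio is the conditional MLE solving
`E[X|ψ] = x` under the Fisher noncentral hypergeometric (computed from a
log-space pmf over the support — numerically stable at extreme odds); the
95% CI inverts the one-sided exact tests at α/2, with one-sided intervals
when a margin pins the count (sample OR is also reported). On the printed
subtype × covariate tables this reproduces the published one-decimal odds
ratios, including the conditional-MLE shrinkage (2.6 where the sample OR
is 2.67) and the `[1.3, ∞)` interval of the all-or-none grade table.

`cox_ph` is a Newton–Raphson maximiser of the Efron-tie partial likelihood
with step halving far from the optimum and pure Newton steps near it
(the log-likelihood change falls below float resolution before the
gradient does); convergence requires gradient sup-norm < 1e−8, and
separation or non-convergence raises with a diagnostic. Wald tests and
CIs come from the observed information. Kaplan–Meier estimation and the
log-rank statistic are delegated to `lifelines`. Survival records pass
through administrative censoring at five time-units before modelling.

Burden dichotomisation (`maxstat`) scans midpoints between distinct burden
values, keeps both arms at ≥ 20% of the cohort, and selects the cut
maximising the log-rank statistic; a fixed user threshold is the
alternative. Maximally selected statistics overfit by construction, so the
achieved statistic is reported alongside the threshold and the synthetic
suite checks threshold recovery, not significance. Combined strata build
the four loss × LOH groups and contrast low/low against the union of the
rest, plus within-subtype burden contrasts.

## Synthetic cohort generator

The generator defines the conditions every recovery test runs under.
Defaults: 64 tumours (44% active / 56% deficient — a 28/36 split), 15
references, a 5-chromosome × 10 Mb genome with 1000 point-like genes,
planted immune (80 genes) and proliferation (80 genes) programs, 8 random
background sets.

* **Copy number:** per-sample segmentation with exponential segment
  lengths (mean 1.5 Mb, 50 kb floor); per-segment event draws at
  subtype-specific rates (gain/loss/copy-neutral-LOH 0.08/0.05/0.02
  active, 0.22/0.13/0.04 deficient); gains add 1, 2 or 5–12 copies
  (p = 0.6/0.3/0.1), losses drop 1–2 with minor allele 0. On top of the
  random process, the distal 30% of every chromosome is a *recurrent gain
  region* gained wholesale (+1 or +2) with probability 0.12 (active) or
  0.45 (deficient) per chromosome — the recurrent arm-level gains real
  MPNST cohorts show, and the regions that host the proliferation program.
  Deficient tumours are triploid with probability 0.35. The
  disproportionate-LOH subgroup (15% of tumours, drawn from the deficient
  subtype) has copy-neutral LOH planted to a target coverage drawn in
  [0.30, 0.70] with stochastic losses suppressed, so the ≥24%/<6% rule
  holds by construction. References are diploid with a focal (200 kb)
  homozygous deletion at rate 0.14.
* **Expression:** gene baselines N(7, 1); immune genes shifted up by
  `immune_effect` (1.5 log2) in active tumours and references, independent
  of copy number; proliferation genes follow
  `baseline + dosage_slope · log2(CN/ploidy)` (slope 1.0); i.i.d. Gaussian
  noise, sd 0.5. Effect sizes are calibration choices — no empirical
  values exist to copy — picked so the planted signal is strong but not
  trivial
  (the variance filter keeps roughly the planted programs plus a noise
  fringe).
* **Survival:** exponential times with hazard
  `0.12 · 4.0^[deficient] · 1.03^(pct_total_cna)`, administrative
  censoring at 5 time-units plus 10% uniform dropout.

What the generator does **not** emulate: probe-level intensities and BAF,
tumour purity and subclonality, correlated (co-regulated) expression noise,
batch effects, and the long tail of real gene-length variation. Passing
recovery tests therefore demonstrates correctness of the procedures under
the stated statistical structure, not performance on raw array data.

## Numerical choices and problem sizes

Seeds propagate from a single integer through `numpy.random.default_rng`;
identical seeds give byte-identical cohorts and pipeline outputs. The
segmentation DP is exact; root-finding for the conditional-MLE OR and
exact CI brackets log-odds in ±50 with xtol 1e−10/1e−12. Recovery checks
use 10 cohorts of 64 tumours for subtyping and concurrency, 3 null
cohorts, n = 2000 for Cox hazard-ratio recovery, 2000 replicates for
competitive-test calibration, and full enumeration for the segmentation
(length ≤ 12) and exact-test (table total ≤ 20) oracles — sizes chosen so
the whole suite runs in a few minutes on one CPU while keeping
Monte-Carlo error well inside the asserted margins.

## Known limitations

* ASCAT-style purity/ploidy estimation, GISTIC recurrence q-values and
  probe-level preprocessing are out of scope; allele-specific segments are
  consumed as input.
* The competitive test's gene-level statistic (rank-sum z) differs from
  limma's moderated t; borderline sets can rank differently.
* The "vs median" 2×2 construction for set concurrency is one explicit
  reading of an under-specified comparison; the flagged-set list is stable
  for clearly enriched sets but the exact p-values depend on the
  construction.
* Maximally selected dichotomisation thresholds are descriptive, not
  inferential, and the per-gene Cox contrasts in target nomination are
  unadjusted single-gene models.
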