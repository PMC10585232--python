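# mpnstkit

Integrated DNA copy-number and transcriptomic analysis of malignant
peripheral nerve sheath tumours (MPNSTs), built as a reusable, fully tested
pipeline. MPNST is a rare, aggressive sarcoma in which roughly half of
tumours lose PRC2 activity, carry complex genomes and follow an aggressive
course; the package implements the analysis stack such a study needs:

* **Copy-number layer** — exact least-squares piecewise-constant
  segmentation (penalised DP), ploidy-relative calling of gains, losses,
  amplification (≥5 copies over ploidy), high-level amplification (≥10),
  homozygous deletion and LOH (minor allele = 0), gene-level mapping, and
  genome-burden statistics including the *disproportionate-LOH* rule
  (LOH ≥ 24% of the genome with losses < 6%).
* **Transcriptomic layer** — variance filtering (log2 variance > 0.3),
  two-subtype discovery by consensus non-negative matrix factorization,
  immune-score-based naming (*immune active* vs *immune deficient*), PCA
  diagnostics, rank-sum differential expression with BH FDR, a
  camera-style competitive gene-set test with variance-inflation factor
  `VIF = 1 + (m−1)·ρ̄`, and GSVA-style single-sample enrichment scores.
* **Integration layer** — gene-wise *concurrency* calls between copy number
  and expression: a gene is concurrent (gain+up or loss+down) when ≥ 5
  samples carry the aberration, aberrant-vs-neutral expression differs at
  rank-sum FDR < 0.05 with |median log2 difference| > 0.5, and expression
  correlates positively with copy number (Spearman ρ > 0, FDR < 0.05);
  plus gene-set concurrency enrichment, candidate intersections
  (differential ∩ concurrent ∩ gained in > 20% of tumours) and loss/LOH
  target nomination (aberration-frequency difference > 40% between burden
  strata, cancer-critical, concurrency-passed).
* **Clinical statistics layer** — exact 2×2 inference in the R
  `fisher.test` convention (two-sided exact p, conditional-MLE odds ratio
  under the noncentral hypergeometric, exact CI by test inversion),
  Wilcoxon rank-sum, Spearman/BH, Cox proportional hazards (Newton–Raphson
  on the Efron partial likelihood, Wald tests), Kaplan–Meier curves,
  burden dichotomisation by maximally selected log-rank statistic and
  combined loss × LOH survival strata with five-year administrative
  censoring.
* **Synthetic cohorts** — a generator that emulates the study's
  statistical structure (two latent subtypes at 44%/56% with an immune
  program independent of copy number and a dosage-driven proliferation
  program, higher burden and triploidy in the deficient subtype, a ~15%
  copy-neutral-LOH subgroup, near-diploid references, proportional-hazards
  survival), so every stage is testable without any download.

## Worked example

Run the staged analysis (each script is a thin driver over the library and
writes its tables under `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_copy_number_burden.py
python analysis/03_subtype_discovery.py
python analysis/04_geneset_enrichment.py
python analysis/05_cna_expression_integration.py
python analysis/06_survival_analysis.py
```

With the default seed the run prints, among other things:

```
subtype
immune_deficient    36
immune_active       28
triploid tumours: 14, disproportionate-LOH subgroup: 10
...
median burden (% of genome) by latent subtype:
                  pct_gain  pct_loss  pct_total_cna  pct_loh
immune_active          9.2       4.7           15.4      7.3
immune_deficient      24.8       6.9           35.2     18.9
disproportionate-LOH flags: 10 (planted: 10)
...
adjusted Rand index vs planted subtypes: 1.000
...
evaluated 257 variable genes; 67 gain+up, 47 loss+down concurrent
planted dosage genes recovered: 76/80
gene sets with excess concurrency over the median (p < 0.01): ['PROLIFERATION_PROGRAM']
...
deficient vs active subtype: HR 7.16 [3.35-15.32], Wald p 3.8e-07 (49 events in 64)
low/low vs any-high: HR 3.25, Wald p 0.00014
```

Reading: the unsupervised subtyping recovers the planted 28/36 split
exactly; the deficient subtype carries a higher genome-wide burden; the
concurrency procedure recovers 76 of 80 planted dosage genes and flags the
proliferation program — not the immune program — as copy-number driven;
and both the subtype and the combined loss/LOH burden stratify survival.

The same flow is available as one orchestrated command with a YAML config:

```bash
mpnstkit template-config > config.yaml
mpnstkit run --config config.yaml --outdir results/run --seed 7
mpnstkit report --outdir results/run
```

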