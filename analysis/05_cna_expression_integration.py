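"""Stage 5 — gene-wise copy-number / expression concurrency.

Maps segments onto genes, calls concurrent gain+up / loss+down genes under
the integration thresholds (>= 5 aberrant samples, rank-sum FDR < 0.05,
|median log2 difference| > 0.5, Spearman rho > 0 at FDR < 0.05), tests gene
sets for excess concurrency over the median, and intersects subtype-up
genes with concurrency and gain frequency > 20% into a candidate list.
"""

from pathlib import Path

import pandas as pd

from mpnstkit.copynumber import map_genes_to_cn
from mpnstkit.enrichment import differential_expression
from mpnstkit.integration import (call_concurrency, concurrent_genes,
                                  geneset_concurrency_enrichment,
                                  intersect_candidates)
from mpnstkit.io import write_table
from mpnstkit.synthetic import read_cohort

COHORT = Path("results/cohort")
SUBTYPES = Path("results/subtypes.tsv")


def main() -> None:
    cohort = read_cohort(COHORT)
    gene_cn = map_genes_to_cn(cohort.segmented_profiles, cohort.gene_models)
    calls = call_concurrency(gene_cn, cohort.expression)
    write_table(calls, Path("results/concurrency_calls.tsv"))
    gain_up = concurrent_genes(calls, "gain_up")
    loss_down = concurrent_genes(calls, "loss_down")
    dosage = set(cohort.truth.dosage_genes)
    hits = set(concurrent_genes(calls))
    print(f"evaluated {calls['gene'].nunique()} variable genes; "
          f"{len(gain_up)} gain+up, {len(loss_down)} loss+down concurrent")
    print(f"planted dosage genes recovered: {len(hits & dosage)}/"
          f"{len(dosage & set(calls['gene']))}")

    enrich = geneset_concurrency_enrichment(calls, cohort.gene_sets)
    write_table(enrich, Path("results/concurrency_set_enrichment.tsv"))
    flagged = enrich[enrich["flagged"]]["gene_set"].tolist()
    print(f"gene sets with excess concurrency over the median (p < 0.01): {flagged}")

    labels = pd.read_csv(SUBTYPES, sep="\t").set_index("sample")["subtype"]
    deficient = list(labels.index[labels == "immune_deficient"])
    active = list(labels.index[labels == "immune_active"])
    de = differential_expression(cohort.expression, deficient, active)
    tumours = set(cohort.truth.samples["sample"])
    gain_freq = gene_cn.aberration_frequency("gain", samples=sorted(tumours))
    cands = intersect_candidates(de.significant(direction="up"), gain_up, gain_freq)
    print(f"candidate targets (up in deficient AND concurrent AND gained in >20%): "
          f"{len(cands['candidates'])}; venn {cands['venn']}")
    write_table(pd.DataFrame({"gene": cands["candidates"]}),
                Path("results/candidate_genes.tsv"))


if __name__ == "__main__":
    main()
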