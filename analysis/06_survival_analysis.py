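"""Stage 6 — survival stratification and loss/LOH target nomination.

Five-year disease-specific survival by transcriptomic subtype (Cox with
Wald tests), burden dichotomisation by maximally selected log-rank
statistic, combined loss x LOH strata, and nomination of cancer-critical
loss/LOH targets within the high-burden deficient stratum.
"""

from pathlib import Path

import pandas as pd

from mpnstkit.clinstats import (apply_administrative_censoring, combined_strata,
                                cox_ph, dichotomize_burden, km_curve)
from mpnstkit.copynumber import map_genes_to_cn
from mpnstkit.integration import call_concurrency, nominate_loss_targets
from mpnstkit.io import write_table
from mpnstkit.synthetic import read_cohort

COHORT = Path("results/cohort")
SUBTYPES = Path("results/subtypes.tsv")
BURDEN = Path("results/burden.tsv")


def main() -> None:
    cohort = read_cohort(COHORT)
    labels = pd.read_csv(SUBTYPES, sep="\t").set_index("sample")["subtype"]
    burdens = pd.read_csv(BURDEN, sep="\t").set_index("sample")
    survival = apply_administrative_censoring(
        cohort.clinical[cohort.clinical["group"] == "tumour"])

    rec = survival.merge(labels.rename("subtype"), left_on="sample", right_index=True)
    rec["deficient"] = (rec["subtype"] == "immune_deficient").astype(float)
    cox = cox_ph(rec, ["deficient"])
    row = cox.table.loc["deficient"]
    print(f"deficient vs active subtype: HR {row['hr']:.2f} "
          f"[{row['ci_low']:.2f}-{row['ci_high']:.2f}], Wald p {row['wald_p']:.2g} "
          f"({cox.n_events} events in {cox.n})")
    write_table(cox.table.reset_index(names="covariate"),
                Path("results/survival_subtype_cox.tsv"))

    splits = {}
    for kind in ("pct_gain", "pct_loss", "pct_loh"):
        out = dichotomize_burden(burdens[kind], survival)
        splits[kind] = out["labels"]
        print(f"{kind}: maxstat threshold {out['threshold']:.1f}% "
              f"(log-rank statistic {out['statistic']:.1f})")
    strata = combined_strata(splits["pct_loss"], splits["pct_loh"], survival,
                             gain_labels=splits["pct_gain"], subtype_labels=labels)
    print("loss x LOH strata sizes:", strata["strata_sizes"])
    contrast = strata["low_vs_rest"].iloc[0]
    print(f"low/low vs any-high: HR {contrast['hr_b_vs_a']:.2f}, "
          f"Wald p {contrast['wald_p']:.2g}")

    deficient = list(labels.index[labels == "immune_deficient"])
    lossloh = (burdens["pct_loss"] + burdens["pct_loh"]).rename("burden")
    split = dichotomize_burden(lossloh,
                               survival[survival["sample"].isin(deficient)])
    high = [s for s in deficient if split["labels"].get(s) == "high"]
    low = [s for s in deficient if split["labels"].get(s) == "low"]
    gene_cn = map_genes_to_cn(cohort.segmented_profiles, cohort.gene_models)
    calls = call_concurrency(gene_cn, cohort.expression)
    cancer_list = cohort.truth.dosage_genes + cohort.truth.immune_genes
    noms = nominate_loss_targets(high, low, gene_cn, cohort.expression, survival,
                                 cancer_list, calls)
    write_table(noms, Path("results/loss_target_nominations.tsv"))
    nominated = noms[noms["nominated"]]
    print(f"nominated loss/LOH targets ({len(high)} high vs {len(low)} low "
          f"deficient tumours): {len(nominated)}")
    print("wrote results/survival_subtype_cox.tsv, loss_target_nominations.tsv")


if __name__ == "__main__":
    main()
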