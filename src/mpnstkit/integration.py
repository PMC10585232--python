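"""Gene-wise integration of copy number and expression.

A gene is called *concurrent* in a direction (gain with up-regulation, or
loss with down-regulation) when, across tumours with both data levels:

* at least ``min_aberrant_samples`` tumours carry the aberration (default 5);
* expression differs between aberrant and copy-neutral tumours at
  ``FDR < 0.05`` by the Wilcoxon rank-sum test, with a median log2
  difference exceeding 0.5 in the concordant direction;
* the gene's expression correlates positively with its continuous copy
  number across all tumours (Spearman rho > 0, FDR < 0.05).

Both FDR families (rank-sum and correlation) use BH across all evaluated
gene-direction pairs jointly.  On top of the per-gene calls the module
offers gene-set concurrency enrichment against the median set proportion,
candidate intersection (differentially expressed AND concurrent AND gained
in more than 20% of tumours), and loss/LOH target nomination in
burden-defined strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, spearmanr

from .clinstats import cox_ph, fisher_one_sided_greater
from .containers import ExpressionMatrix
from .copynumber import GeneCNMatrix
from .enrichment import bh_adjust, differential_expression
from .errors import ArgumentError, ConfigurationError, DataError


@dataclass
class IntegrationConfig:
    min_aberrant_samples: int = 5
    de_fdr_max: float = 0.05
    min_abs_median_diff: float = 0.5
    rho_min: float = 0.0            # strict >
    rho_fdr_max: float = 0.05
    expr_variance_min: float = 0.3

    def __post_init__(self) -> None:
        if self.min_aberrant_samples < 1:
            raise ConfigurationError("min_aberrant_samples must be >= 1")
        for name in ("de_fdr_max", "rho_fdr_max"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.min_abs_median_diff < 0:
            raise ConfigurationError("min_abs_median_diff must be non-negative")


GAIN_CALLS = ["gain", "amp", "high_amp"]
LOSS_CALLS = ["loss", "homdel"]


def call_concurrency(gene_cn: GeneCNMatrix, expr: ExpressionMatrix,
                     config: IntegrationConfig | None = None,
                     samples: list[str] | None = None) -> pd.DataFrame:
    """Evaluate gain_up / loss_down concurrency for every variable gene.

    Returns one row per evaluated gene-direction pair with the test
    statistics and the final ``passed`` flag; genes skipped (too few
    aberrant or no neutral samples) are absent with their reason recorded in
    the ``skipped`` attribute of the returned frame (``df.attrs``).
    """
    cfg = config or IntegrationConfig()
    shared = [s for s in (samples or expr.tumour_samples()) if s in gene_cn.samples]
    if len(shared) < 10:
        raise ArgumentError(f"need >= 10 shared samples, got {len(shared)}")
    variances = expr.values[shared].var(axis=1, ddof=1)
    genes = [g for g in gene_cn.genes
             if g in variances.index and variances[g] > cfg.expr_variance_min]
    calls = gene_cn.calls[shared]
    # correlation uses ploidy-relative copy number (the segmentation estimates
    # are relative to the genome-wide level), so triploid genomes do not
    # dilute the dosage signal
    cont = gene_cn.continuous[shared] / gene_cn.ploidy[shared]
    evalues = expr.values[shared]
    rows, skipped = [], {}
    for gene in genes:
        gcalls = calls.loc[gene].to_numpy()
        e = evalues.loc[gene].to_numpy(dtype=float)
        cn = cont.loc[gene].to_numpy(dtype=float)
        neutral = gcalls == "neutral"
        if neutral.sum() == 0:
            skipped[gene] = "no copy-neutral samples"
            continue
        ok = np.isfinite(cn)
        if ok.sum() >= 3 and np.ptp(cn[ok]) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho, rho_p = spearmanr(cn[ok], e[ok])
        else:
            rho, rho_p = np.nan, np.nan
        for direction, members in (("gain_up", GAIN_CALLS), ("loss_down", LOSS_CALLS)):
            aberrant = np.isin(gcalls, members)
            n_ab = int(aberrant.sum())
            if n_ab < cfg.min_aberrant_samples:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                de_p = float(mannwhitneyu(e[aberrant], e[neutral],
                                          alternative="two-sided",
                                          method="asymptotic").pvalue)
            med_diff = float(np.median(e[aberrant]) - np.median(e[neutral]))
            rows.append({"gene": gene, "direction": direction, "n_aberrant": n_ab,
                         "n_neutral": int(neutral.sum()), "de_p": de_p,
                         "median_diff": med_diff, "rho": float(rho),
                         "rho_p": float(rho_p)})
    table = pd.DataFrame(rows, columns=["gene", "direction", "n_aberrant", "n_neutral",
                                        "de_p", "median_diff", "rho", "rho_p"])
    if not table.empty:
        table["de_fdr"] = bh_adjust(table["de_p"])
        table["rho_fdr"] = bh_adjust(table["rho_p"])
        concordant = np.where(table["direction"] == "gain_up",
                              table["median_diff"] > cfg.min_abs_median_diff,
                              table["median_diff"] < -cfg.min_abs_median_diff)
        table["passed"] = (
            (table["de_fdr"] < cfg.de_fdr_max)
            & concordant
            & (table["rho"] > cfg.rho_min)
            & (table["rho_fdr"] < cfg.rho_fdr_max)
        )
    else:
        table["de_fdr"] = table["rho_fdr"] = table["passed"] = pd.Series(dtype=float)
    table.attrs["skipped"] = skipped
    return table


def concurrent_genes(calls: pd.DataFrame, direction: str | None = None) -> list[str]:
    t = calls[calls["passed"].astype(bool)]
    if direction is not None:
        t = t[t["direction"] == direction]
    return sorted(t["gene"].unique())


def geneset_concurrency_enrichment(calls: pd.DataFrame,
                                   gene_sets: dict[str, list[str]],
                                   direction: str = "gain_up",
                                   flag_p: float = 0.01) -> pd.DataFrame:
    """Per-set excess of concurrent genes over the median set proportion.

    Each set's concurrent count ``k`` of ``m`` mapped genes is compared with
    the expected count at the median proportion across sets,
    ``k_med = round(median_prop * m)``, by a one-sided Fisher test on
    ``[[k, m-k], [k_med, m-k_med]]``.
    """
    if len(gene_sets) < 3:
        raise ArgumentError("need at least three gene sets")
    evaluated = set(calls["gene"].unique())
    hits = set(concurrent_genes(calls, direction))
    rows = []
    for name, members in gene_sets.items():
        mapped = [g for g in members if g in evaluated]
        if not mapped:
            continue
        k = sum(g in hits for g in mapped)
        rows.append({"gene_set": name, "n_genes": len(mapped), "n_concurrent": k,
                     "proportion": k / len(mapped)})
    if not rows:
        raise DataError("no gene set overlaps the evaluated genes")
    table = pd.DataFrame(rows)
    median_prop = float(table["proportion"].median())
    ps = []
    for _, row in table.iterrows():
        m, k = int(row["n_genes"]), int(row["n_concurrent"])
        k_med = int(round(median_prop * m))
        ps.append(fisher_one_sided_greater([[k, m - k], [k_med, m - k_med]]))
    table["median_proportion"] = median_prop
    table["p"] = ps
    table["flagged"] = table["p"] < flag_p
    return table.sort_values("p").reset_index(drop=True)


def intersect_candidates(de_up: list[str], concurrent: list[str],
                         gain_freq: pd.Series, freq_min: float = 0.20) -> dict:
    """Candidates = DE-up AND concurrent AND gained in > ``freq_min`` of tumours."""
    set_de = set(de_up)
    set_cc = set(concurrent)
    set_freq = set(gain_freq.index[gain_freq > freq_min])
    candidates = sorted(set_de & set_cc & set_freq)
    return {
        "candidates": candidates,
        "n_de_up": len(set_de), "n_concurrent": len(set_cc),
        "n_frequent_gain": len(set_freq),
        "venn": {"de&concurrent": len(set_de & set_cc),
                 "de&frequent": len(set_de & set_freq),
                 "concurrent&frequent": len(set_cc & set_freq),
                 "all": len(candidates)},
    }


def nominate_loss_targets(high_stratum: list[str], low_stratum: list[str],
                          gene_cn: GeneCNMatrix, expr: ExpressionMatrix,
                          survival: pd.DataFrame, cancer_genes: list[str],
                          concurrency_calls: pd.DataFrame,
                          freq_diff_min: float = 0.40) -> pd.DataFrame:
    """Nominate loss/LOH target genes within a high-burden stratum.

    ``high_stratum`` / ``low_stratum`` are the immune-deficient tumours with
    high and low loss/LOH burden.  A gene is nominated when its loss-or-LOH
    frequency is more than ``freq_diff_min`` higher in the high stratum, it
    is on the cancer-critical list, and it passed loss_down concurrency.
    Per-gene Cox contrasts (neutral vs loss/LOH) and a high-vs-low-stratum
    differential expression are attached for reporting.
    """
    if len(high_stratum) < 3 or len(low_stratum) < 3:
        raise ArgumentError("each stratum needs at least three samples")
    freq_high = gene_cn.aberration_frequency("loss_or_loh", samples=high_stratum)
    freq_low = gene_cn.aberration_frequency("loss_or_loh", samples=low_stratum)
    cancer = set(cancer_genes)
    loss_cc = set(concurrent_genes(concurrency_calls, "loss_down"))
    both = high_stratum + low_stratum
    de = differential_expression(
        expr.subset_genes([g for g in gene_cn.genes if g in expr.values.index]),
        high_stratum, low_stratum)
    surv = survival.set_index("sample")
    rows = []
    for gene in gene_cn.genes:
        fh, fl = float(freq_high.get(gene, np.nan)), float(freq_low.get(gene, np.nan))
        diff = fh - fl
        nominated = (diff > freq_diff_min) and gene in cancer and gene in loss_cc
        hr = hr_p = np.nan
        if nominated:
            aberrant = (gene_cn.calls.loc[gene, both].isin(LOSS_CALLS)
                        | gene_cn.loh.loc[gene, both])
            rec = surv.reindex(both)[["time", "event"]].copy()
            rec["aberrant"] = aberrant.astype(float).to_numpy()
            rec = rec.dropna()
            try:
                res = cox_ph(rec, ["aberrant"])
                hr = res.hr("aberrant")
                hr_p = float(res.table.loc["aberrant", "wald_p"])
            except DataError:
                pass
        row = {"gene": gene, "freq_high": fh, "freq_low": fl, "freq_diff": diff,
               "is_cancer_critical": gene in cancer, "concurrency": gene in loss_cc,
               "nominated": bool(nominated), "hr": hr, "hr_p": hr_p}
        if gene in de.table.index:
            row["de_logfc"] = float(de.table.loc[gene, "effect"])
            row["de_p"] = float(de.table.loc[gene, "p"])
        else:
            row["de_logfc"] = row["de_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
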