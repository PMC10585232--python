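"""Differential expression and gene-set enrichment.

Three layers:

* :func:`differential_expression` — per-gene two-group comparison by the
  Wilcoxon rank-sum test (exact null when the smaller group has <= 8 samples
  and no ties, tie-corrected normal approximation otherwise), effect size as
  the difference of group medians on the log2 scale, BH-adjusted p-values.
* :func:`competitive_set_test` — a competitive gene-set test on per-gene
  z-scores.  The set mean is compared with the non-set mean by a two-sample
  t statistic whose set-variance term is inflated by ``VIF = 1 + (m-1)*rho``
  to account for inter-gene correlation; with ``rho = 0`` it reduces to the
  ordinary equal-variance two-sample test.
* :func:`ssgsva` — single-sample enrichment scores in the GSVA style:
  per-gene Gaussian-kernel CDF across samples (bandwidth sd/4), per-sample
  gene ranking by that statistic, symmetric rank weights ``|p/2 - rank|``,
  and a weighted Kolmogorov–Smirnov-like random walk whose score is the
  maximum positive plus the maximum negative deviation (signed sum).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm, rankdata, t as t_dist
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix
from .errors import ArgumentError, DataError


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (NaN-safe)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class DEResult:
    table: pd.DataFrame  # index gene; columns effect, p, fdr

    def significant(self, fdr_max: float = 0.05, effect_min: float = 0.0,
                    direction: str | None = None) -> list[str]:
        t = self.table
        keep = (t["fdr"] < fdr_max) & (t["effect"].abs() > effect_min)
        if direction == "up":
            keep &= t["effect"] > 0
        elif direction == "down":
            keep &= t["effect"] < 0
        return list(t.index[keep])


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p for one gene, following the stated exact/approx rule."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and no_ties) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def differential_expression(expr: ExpressionMatrix, group_a: list[str],
                            group_b: list[str]) -> DEResult:
    """Per-gene rank-sum comparison of two disjoint sample groups (A minus B)."""
    if set(group_a) & set(group_b):
        raise ArgumentError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ArgumentError("both groups need at least two samples")
    a = expr.values[group_a].to_numpy(dtype=float)
    b = expr.values[group_b].to_numpy(dtype=float)
    effect = np.median(a, axis=1) - np.median(b, axis=1)
    small = min(a.shape[1], b.shape[1]) <= 8
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_async = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                               axis=1).pvalue
    p = np.asarray(p_async, dtype=float)
    for i in range(a.shape[0]):  # constant genes and small exact cases
        pooled = np.concatenate([a[i], b[i]])
        if np.ptp(pooled) == 0:
            p[i] = 1.0
        elif small and len(np.unique(pooled)) == len(pooled):
            p[i] = _ranksum_p(a[i], b[i])
    table = pd.DataFrame({"effect": effect, "p": p, "fdr": bh_adjust(p)},
                         index=expr.values.index)
    return DEResult(table=table)


def gene_zscores(expr: ExpressionMatrix, group_a: list[str],
                 group_b: list[str]) -> pd.Series:
    """Signed per-gene z-scores from the tie-corrected rank-sum statistic (A vs B)."""
    a = expr.values[group_a].to_numpy(dtype=float)
    b = expr.values[group_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    pooled = np.concatenate([a, b], axis=1)
    ranks = rankdata(pooled, axis=1)
    u = ranks[:, :na].sum(axis=1) - na * (na + 1) / 2.0
    mu = na * nb / 2.0
    n = na + nb
    tie_term = np.zeros(pooled.shape[0])
    for i in range(pooled.shape[0]):
        _, counts = np.unique(pooled[i], return_counts=True)
        tie_term[i] = np.sum(counts**3 - counts)
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-12))
    z = (u - mu) / sigma
    z[sigma2 <= 1e-12] = 0.0
    return pd.Series(z, index=expr.values.index)


def estimate_set_correlation(expr: ExpressionMatrix, set_genes: list[str],
                             groups: list[list[str]] | None = None) -> float:
    """Mean pairwise Pearson correlation of the set genes' residuals, floored at 0.

    Residuals are taken about per-group means when sample groups are given
    (so a planted group effect does not inflate the estimate), else about
    gene means.
    """
    genes = [g for g in set_genes if g in expr.values.index]
    if len(genes) < 2:
        return 0.0
    x = expr.values.loc[genes].to_numpy(dtype=float)
    if groups:
        resid = np.empty_like(x)
        cols = list(expr.values.columns)
        for grp in groups:
            idx = [cols.index(s) for s in grp]
            resid[:, idx] = x[:, idx] - x[:, idx].mean(axis=1, keepdims=True)
    else:
        resid = x - x.mean(axis=1, keepdims=True)
    sd = resid.std(axis=1)
    keep = sd > 0
    if keep.sum() < 2:
        return 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(resid[keep])
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    off = off[np.isfinite(off)]
    if off.size == 0:
        return 0.0
    return float(max(0.0, off.mean()))


@dataclass
class SetTestResult:
    n_genes: int
    delta: float
    statistic: float
    p: float
    direction: str
    vif: float


def competitive_set_test(scores: pd.Series, set_genes: list[str],
                         mean_correlation: float = 0.0) -> SetTestResult:
    """Directional competitive test of set vs non-set gene statistics."""
    genes = set(scores.index)
    members = [g for g in set_genes if g in genes]
    m = len(members)
    if m < 2:
        raise ArgumentError("set must map to at least two scored genes")
    if m >= len(genes):
        raise ArgumentError("set covers every scored gene: no competitive complement")
    in_set = scores.index.isin(members)
    z = scores.to_numpy(dtype=float)
    zs, zr = z[in_set], z[~in_set]
    p_total = z.size
    delta = zs.mean() - zr.mean()
    df = p_total - 2
    pooled_var = ((zs.var(ddof=1) * (m - 1) if m > 1 else 0.0)
                  + zr.var(ddof=1) * (zr.size - 1)) / df
    vif = 1.0 + (m - 1) * max(0.0, mean_correlation)
    se = np.sqrt(pooled_var * (vif / m + 1.0 / zr.size))
    if se == 0:
        stat, p = 0.0, 1.0
    else:
        stat = delta / se
        p = float(2.0 * t_dist.sf(abs(stat), df))
    return SetTestResult(n_genes=m, delta=float(delta), statistic=float(stat), p=p,
                         direction="up" if delta > 0 else "down", vif=float(vif))


def camera_table(expr: ExpressionMatrix, group_a: list[str], group_b: list[str],
                 gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Competitive enrichment of every set for A-vs-B, BH-adjusted."""
    scores = gene_zscores(expr, group_a, group_b)
    rows = []
    for name, members in gene_sets.items():
        mapped = [g for g in members if g in scores.index]
        if len(mapped) < 2 or len(mapped) >= len(scores):
            continue
        rho = estimate_set_correlation(expr, mapped, groups=[group_a, group_b])
        res = competitive_set_test(scores, mapped, rho)
        rows.append({"gene_set": name, "n_genes": res.n_genes, "delta": res.delta,
                     "direction": res.direction, "p": res.p, "vif": res.vif})
    if not rows:
        raise DataError("no gene set overlapped the expression matrix")
    table = pd.DataFrame(rows)
    table["fdr"] = bh_adjust(table["p"])
    return table.sort_values("p").reset_index(drop=True)


def ssgsva(expr: ExpressionMatrix, gene_sets: dict[str, list[str]],
           tau: float = 1.0) -> pd.DataFrame:
    """Single-sample enrichment scores (gene sets x samples)."""
    values = expr.values
    p, n = values.shape
    if n < 3:
        raise ArgumentError("single-sample scoring needs at least three samples")
    x = values.to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1)
    h = np.maximum(sd, 1e-8) / 4.0  # Gaussian kernel bandwidth, GSVA convention
    z = np.empty_like(x)
    for i in range(p):
        z[i] = norm.cdf((x[i][:, None] - x[i][None, :]) / h[i]).mean(axis=1)
    # per-sample ordering by decreasing kernel-CDF statistic
    order = np.argsort(-z, axis=0, kind="stable")
    ranks = np.empty_like(order)
    col = np.arange(n)
    ranks[order, col] = np.arange(1, p + 1)[:, None]
    weight = np.abs(p / 2.0 - ranks) ** tau

    gene_index = {g: i for i, g in enumerate(values.index)}
    scores = {}
    skipped = []
    for name, members in gene_sets.items():
        idx = [gene_index[g] for g in members if g in gene_index]
        m = len(idx)
        if m < 2:
            skipped.append(name)
            continue
        if m >= p:
            raise ArgumentError(f"set {name!r} covers all genes: walk undefined")
        mask = np.zeros(p, dtype=bool)
        mask[idx] = True
        set_scores = np.empty(n)
        for j in range(n):
            ordered_mask = mask[order[:, j]]
            w = weight[order[:, j], j] * ordered_mask
            inc = np.cumsum(w) / w.sum()
            dec = np.cumsum(~ordered_mask) / (p - m)
            v = inc - dec
            set_scores[j] = v.max() + v.min()
        scores[name] = set_scores
    if skipped:
        warnings.warn(f"skipped sets with <2 mapped genes: {skipped}")
    if not scores:
        raise DataError("every gene set was skipped: nothing to score")
    return pd.DataFrame(scores, index=values.columns).T
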