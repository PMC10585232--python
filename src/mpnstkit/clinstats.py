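"""Clinical statistics: exact 2x2 inference, rank tests, survival models.

The 2x2 machinery reproduces the R ``fisher.test`` conventions: the
two-sided p-value sums central-hypergeometric table probabilities not
exceeding the observed one; the odds ratio is the *conditional MLE* under
the noncentral hypergeometric distribution given all margins (solving
``E[X | psi] = x``); the exact 95% CI inverts the one-sided exact tests at
alpha/2.  Cox proportional-hazards models (Efron tie handling, Wald tests)
and Kaplan-Meier estimation are delegated to ``lifelines`` behind this
module's interface.  Survival follows a five-year disease-specific window:
events after five time-units are administratively censored at five.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import mannwhitneyu, spearmanr

from .enrichment import bh_adjust
from .errors import ArgumentError, DataError


# ---------------------------------------------------------------------------
# exact 2x2 inference
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    table: np.ndarray
    or_cmle: float
    ci_low: float
    ci_high: float
    p: float
    or_sample: float


def _nchg_pmf(M: int, n: int, N: int, log_psi: float) -> tuple[np.ndarray, np.ndarray]:
    """Fisher noncentral hypergeometric pmf over its support, in log space."""
    lo, hi = max(0, N - (M - n)), min(n, N)
    support = np.arange(lo, hi + 1)
    logw = (gammaln(n + 1) - gammaln(support + 1) - gammaln(n - support + 1)
            + gammaln(M - n + 1) - gammaln(N - support + 1)
            - gammaln(M - n - N + support + 1)
            + support * log_psi)
    return support, np.exp(logw - logsumexp(logw))


def _cmle_or(x: int, M: int, n: int, N: int) -> float:
    lo, hi = max(0, N - (M - n)), min(n, N)
    if x == lo:
        return 0.0
    if x == hi:
        return np.inf

    def mean_shift(log_psi: float) -> float:
        support, pmf = _nchg_pmf(M, n, N, log_psi)
        return float((support * pmf).sum()) - x

    return float(np.exp(brentq(mean_shift, -50.0, 50.0, xtol=1e-12)))


def _exact_ci(x: int, M: int, n: int, N: int, alpha: float = 0.05) -> tuple[float, float]:
    lo, hi = max(0, N - (M - n)), min(n, N)

    def sf_at(log_psi: float) -> float:  # P(X >= x | psi)
        support, pmf = _nchg_pmf(M, n, N, log_psi)
        return float(pmf[support >= x].sum())

    def cdf_at(log_psi: float) -> float:  # P(X <= x | psi)
        support, pmf = _nchg_pmf(M, n, N, log_psi)
        return float(pmf[support <= x].sum())

    if x == lo:
        ci_low = 0.0
    else:
        ci_low = float(np.exp(brentq(lambda lp: sf_at(lp) - alpha / 2, -36.0, 36.0,
                                     xtol=1e-10)))
    if x == hi:
        ci_high = np.inf
    else:
        ci_high = float(np.exp(brentq(lambda lp: cdf_at(lp) - alpha / 2, -36.0, 36.0,
                                      xtol=1e-10)))
    return ci_low, ci_high


def fisher_exact_2x2(table) -> ContingencyResult:
    """Two-sided exact test with conditional-MLE odds ratio and exact 95% CI."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ArgumentError("need a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DataError("degenerate table: a zero row or column margin")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    M, n, N, x = a + b + c + d, a + c, a + b, a
    p = float(_scipy_fisher(t, alternative="two-sided")[1])
    or_cmle = _cmle_or(x, M, n, N)
    ci_low, ci_high = _exact_ci(x, M, n, N)
    or_sample = np.inf if b * c == 0 else (a * d) / (b * c)
    if b * c == 0 and a * d == 0:
        or_sample = np.nan
    return ContingencyResult(table=t, or_cmle=or_cmle, ci_low=ci_low,
                             ci_high=ci_high, p=min(p, 1.0), or_sample=float(or_sample))


def fisher_one_sided_greater(table) -> float:
    """One-sided (enrichment) exact p-value for a 2x2 table."""
    t = np.asarray(table, dtype=int)
    return float(_scipy_fisher(t, alternative="greater")[1])


# ---------------------------------------------------------------------------
# rank and correlation tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p; exact when min(n) <= 8 with no ties, else
    tie-corrected normal approximation with continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ArgumentError("both samples need at least one value")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (min(x.size, y.size) <= 8 and no_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def spearman_bh(pairs: list[tuple[np.ndarray, np.ndarray]]) -> pd.DataFrame:
    """Spearman rho and p per pair (t-approximation), BH-adjusted across the list."""
    rows = []
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 3 or x.size != y.size:
            raise ArgumentError("each pair needs >= 3 aligned values")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"rho": np.nan, "p": np.nan})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho, p = spearmanr(x, y)
        rows.append({"rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"])
    return out


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    table: pd.DataFrame   # index covariate; columns coef, hr, ci_low, ci_high, wald_p
    log_likelihood: float
    n: int
    n_events: int

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


@dataclass
class KMCurve:
    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    censor_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def survival_at(self, time: float) -> float:
        idx = np.searchsorted(self.times, time, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def apply_administrative_censoring(records: pd.DataFrame, horizon: float = 5.0
                                   ) -> pd.DataFrame:
    """Censor any follow-up beyond the horizon (five-year disease-specific window)."""
    out = records.copy()
    late = out["time"] > horizon
    out.loc[late, "time"] = horizon
    out.loc[late, "event"] = 0
    return out


def _efron_loglik(beta: np.ndarray, x: np.ndarray, times: np.ndarray,
                  events: np.ndarray):
    """Log partial likelihood with Efron tie handling, plus gradient and Hessian.

    Rows must be sorted by increasing time.  For each distinct event time the
    tied events D inside risk set R contribute
    ``sum_D x.beta - sum_{l<d} log(S_R - (l/d) S_D)`` with S the
    exp(x.beta)-weighted sums; gradient/Hessian follow by differentiating the
    weighted log-sum terms.
    """
    n, k = x.shape
    eta = x @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = wx[:, :, None] * x[:, None, :]
    # suffix sums over the risk set (rows i..n-1 share time >= times[i])
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    ll, grad, hess = 0.0, np.zeros(k), np.zeros((k, k))
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        dead = np.arange(i, j)[events[i:j] == 1]
        d = len(dead)
        if d:
            ll += float(eta[dead].sum())
            grad += x[dead].sum(axis=0)
            sd0 = w[dead].sum()
            sd1 = wx[dead].sum(axis=0)
            sd2 = wxx[dead].sum(axis=0)
            for el in range(d):
                f = el / d
                a0 = s0[i] - f * sd0
                a1 = s1[i] - f * sd1
                a2 = s2[i] - f * sd2
                ll -= float(np.log(a0))
                grad -= a1 / a0
                hess -= a2 / a0 - np.outer(a1, a1) / a0**2
        i = j
    return ll, grad, hess


def cox_ph(records: pd.DataFrame, covariates: list[str],
           grad_tol: float = 1e-8, max_iter: int = 100) -> CoxResult:
    """Cox proportional-hazards fit by Newton-Raphson (Efron ties, Wald tests).

    ``records`` needs ``time`` and ``event`` columns; listwise deletion of
    rows with missing covariates mirrors the usual clinical-model practice.
    Convergence requires the gradient sup-norm below ``grad_tol``; monotone
    separation or non-convergence raises with a diagnostic.
    """
    if not covariates:
        raise ArgumentError("no covariates supplied")
    cols = ["time", "event"] + covariates
    data = records[cols].dropna().copy()
    if data.empty or data["event"].sum() == 0:
        raise DataError("no events: Cox model is not identifiable")
    for cov in covariates:
        if data[cov].nunique() < 2:
            raise DataError(f"covariate {cov!r} is constant")
    data = data.sort_values("time", kind="stable")
    x = data[covariates].to_numpy(dtype=float)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    center = x.mean(axis=0)
    xs = (x - center) / scale
    times = data["time"].to_numpy(dtype=float)
    events = data["event"].to_numpy(dtype=int)
    beta = np.zeros(len(covariates))
    ll, grad, hess = _efron_loglik(beta, xs, times, events)
    for _ in range(max_iter):
        if np.abs(grad).max() < grad_tol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise DataError(f"Cox model failed: singular information matrix ({exc})")
        # step halving keeps the partial likelihood monotone far from the
        # optimum; near it the ll change drops below float resolution, so the
        # pure Newton step is taken and quadratic convergence finishes the job
        near_optimum = np.abs(grad).max() < 1e-3
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, hess_new = _efron_loglik(cand, xs, times, events)
            if near_optimum or (np.isfinite(ll_new) and ll_new >= ll - 1e-12):
                break
            step *= 0.5
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        if np.abs(beta).max() > 50:
            raise DataError("Cox model failed to converge: separation suspected "
                            f"(|beta| > 50 for {covariates})")
    else:
        raise DataError(f"Cox model did not converge in {max_iter} iterations "
                        f"(gradient sup-norm {np.abs(grad).max():.2e})")
    cov_mat = np.linalg.inv(-hess)
    beta_raw = beta / scale
    se_raw = np.sqrt(np.diag(cov_mat)) / scale
    z_crit = norm_ppf_975()
    wald_z = beta_raw / se_raw
    table = pd.DataFrame({
        "coef": beta_raw,
        "hr": np.exp(beta_raw),
        "ci_low": np.exp(beta_raw - z_crit * se_raw),
        "ci_high": np.exp(beta_raw + z_crit * se_raw),
        "wald_p": 2.0 * _norm_sf(np.abs(wald_z)),
    }, index=covariates)
    return CoxResult(table=table, log_likelihood=float(ll),
                     n=len(data), n_events=int(events.sum()))


def norm_ppf_975() -> float:
    from scipy.stats import norm
    return float(norm.ppf(0.975))


def _norm_sf(z):
    from scipy.stats import norm
    return norm.sf(z)


def km_curve(records: pd.DataFrame, group_col: str) -> tuple[dict[str, KMCurve], pd.DataFrame]:
    """Kaplan-Meier curve per group plus pairwise Cox hazard ratios."""
    curves: dict[str, KMCurve] = {}
    groups = [g for g in records[group_col].dropna().unique()]
    if not groups:
        raise ArgumentError("no groups to estimate")
    for g in groups:
        sub = records[records[group_col] == g]
        if sub.empty:
            raise ArgumentError(f"empty group {g!r}")
        km = KaplanMeierFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km.fit(sub["time"], sub["event"])
        sf = km.survival_function_
        ev = km.event_table
        curves[str(g)] = KMCurve(
            group=str(g),
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
            at_risk=ev["at_risk"].to_numpy(dtype=float),
            censor_times=sub.loc[sub["event"] == 0, "time"].to_numpy(dtype=float),
        )
    rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            sub = records[records[group_col].isin([ga, gb])].copy()
            sub["_ind"] = (sub[group_col] == gb).astype(float)
            try:
                res = cox_ph(sub, ["_ind"])
                rows.append({"group_a": ga, "group_b": gb,
                             "hr_b_vs_a": res.hr("_ind"),
                             "ci_low": float(res.table.loc["_ind", "ci_low"]),
                             "ci_high": float(res.table.loc["_ind", "ci_high"]),
                             "wald_p": float(res.table.loc["_ind", "wald_p"])})
            except DataError as exc:
                rows.append({"group_a": ga, "group_b": gb, "hr_b_vs_a": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "wald_p": np.nan,
                             "note": str(exc)})
    return curves, pd.DataFrame(rows)


def dichotomize_burden(burdens: pd.Series, records: pd.DataFrame,
                       method: str = "maxstat", threshold: float | None = None,
                       min_group_fraction: float = 0.2) -> dict:
    """Split samples into high/low burden for survival contrasts.

    ``maxstat`` scans candidate cutpoints (midpoints between consecutive
    distinct burden values keeping both arms at ``min_group_fraction`` of the
    cohort) and keeps the one maximising the log-rank statistic; ``fixed``
    applies a user threshold.  Returns threshold, labels and the achieved
    log-rank statistic.
    """
    merged = records.set_index("sample").join(burdens.rename("burden"), how="inner")
    merged = merged.dropna(subset=["burden", "time"])
    if len(merged) < 10:
        raise DataError("need >= 10 samples with survival for dichotomization")
    values = merged["burden"].to_numpy(dtype=float)
    if method == "fixed":
        if threshold is None:
            raise ArgumentError("fixed method needs a threshold")
        labels = np.where(values > threshold, "high", "low")
        if len(set(labels)) < 2:
            raise DataError("fixed threshold leaves an empty group")
        best_thr, best_stat = float(threshold), np.nan
    elif method == "maxstat":
        uniq = np.unique(values)
        if uniq.size < 2:
            raise DataError("constant burden: no admissible threshold")
        min_n = max(1, int(np.ceil(min_group_fraction * len(merged))))
        best_thr, best_stat = None, -np.inf
        for cut in (uniq[:-1] + uniq[1:]) / 2.0:
            hi = values > cut
            if hi.sum() < min_n or (~hi).sum() < min_n:
                continue
            res = logrank_test(merged["time"][hi], merged["time"][~hi],
                               merged["event"][hi], merged["event"][~hi])
            if res.test_statistic > best_stat:
                best_stat, best_thr = float(res.test_statistic), float(cut)
        if best_thr is None:
            raise DataError("no admissible threshold satisfies the group-size floor")
        labels = np.where(values > best_thr, "high", "low")
    else:
        raise ArgumentError(f"unknown method {method!r}")
    return {"threshold": best_thr, "statistic": best_stat,
            "labels": pd.Series(labels, index=merged.index, name="burden_level")}


def combined_strata(loss_labels: pd.Series, loh_labels: pd.Series,
                    records: pd.DataFrame,
                    gain_labels: pd.Series | None = None,
                    subtype_labels: pd.Series | None = None) -> dict:
    """Loss x LOH survival strata and within-subtype burden contrasts.

    Builds the four loss/LOH groups, contrasts the low/low group against the
    union of the other three, and (when subtype labels are given) repeats the
    gain and loss/LOH contrasts within each transcriptomic subtype.
    """
    rec = records.set_index("sample")
    joint = pd.DataFrame({"loss": loss_labels, "loh": loh_labels}).dropna()
    joint = joint.join(rec[["time", "event"]], how="inner").dropna(subset=["time"])
    if joint.empty:
        raise DataError("labels do not cover any survival records")
    joint["stratum"] = joint["loss"] + "/" + joint["loh"]
    joint["any_high"] = np.where((joint["loss"] == "high") | (joint["loh"] == "high"),
                                 "loss_or_loh_high", "both_low")
    if joint["any_high"].nunique() < 2:
        raise DataError("one contrast arm is empty")
    curves, _ = km_curve(joint.reset_index().rename(columns={"index": "sample"}),
                         "stratum")
    joint_reset = joint.reset_index(names="sample")
    _, contrast = km_curve(joint_reset, "any_high")
    out = {"strata_sizes": joint["stratum"].value_counts().to_dict(),
           "curves": curves, "low_vs_rest": contrast}
    if subtype_labels is not None:
        within = {}
        labels_all = {"loss_loh": joint["any_high"]}
        if gain_labels is not None:
            labels_all["gain"] = gain_labels
        for subtype in subtype_labels.dropna().unique():
            members = subtype_labels.index[subtype_labels == subtype]
            for kind, lab in labels_all.items():
                sub = rec.loc[rec.index.intersection(members), ["time", "event"]].copy()
                sub[kind] = lab.reindex(sub.index)
                sub = sub.dropna()
                if sub.empty or sub[kind].nunique() < 2:
                    within[(str(subtype), kind)] = None
                    continue
                _, pair = km_curve(sub.reset_index(names="sample"), kind)
                within[(str(subtype), kind)] = pair
        out["within_subtype"] = within
    return out
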