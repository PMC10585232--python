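"""Copy-number segmentation, calling, gene mapping and burden statistics.

Calls are always made relative to the sample's genome-wide ploidy: a gain is
``total_cn >= ploidy + gain_margin`` and a loss ``total_cn <= ploidy -
loss_margin`` (default margins one integer copy); amplification and
high-level amplification are gains of at least 5 and 10 copies over ploidy;
homozygous deletion is total copy number 0; LOH is minor-allele copy number
0 with at least one remaining copy (and so includes copy-neutral LOH at
``total_cn == ploidy``).  Burden is the percentage of the *covered* genome
carrying each call.  Profiles without integer copy number can be called in
log-ratio mode with symmetric margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SegmentedProfile
from .errors import ArgumentError, DataError

CALL_LEVELS = ["homdel", "loss", "neutral", "gain", "amp", "high_amp"]


@dataclass
class CallThresholds:
    gain_margin: float = 1.0
    loss_margin: float = 1.0
    log_ratio_margin: float = 0.15
    amp_copies: float = 5.0
    high_amp_copies: float = 10.0
    homdel_total: float = 0.0
    mode: str = "integer"  # 'integer' uses total_cn, 'log_ratio' uses log_ratio

    def __post_init__(self) -> None:
        if self.gain_margin <= 0 or self.loss_margin <= 0 or self.log_ratio_margin <= 0:
            raise ArgumentError("margins must be positive")
        if self.amp_copies >= self.high_amp_copies:
            raise ArgumentError("amp_copies must be below high_amp_copies")
        if self.mode not in ("integer", "log_ratio"):
            raise ArgumentError(f"unknown calling mode {self.mode!r}")


@dataclass
class BurdenSummary:
    sample_id: str
    pct_gain: float
    pct_loss: float
    pct_total_cna: float
    pct_loh: float
    disproportionate_loh: bool = False

    def __post_init__(self) -> None:
        for v in (self.pct_gain, self.pct_loss, self.pct_total_cna, self.pct_loh):
            if not 0.0 <= v <= 100.0 + 1e-9:
                raise DataError(f"burden percentage out of range: {v}")


def pcf_segment(signal, gamma: float) -> list[tuple[int, int, float]]:
    """Exact least-squares piecewise-constant fit of a 1-D signal.

    Minimises ``sum((x_i - mean_of_its_segment)^2) + gamma * n_breakpoints``
    globally by dynamic programming over all segmentations (O(n^2)).
    Returns ``(start, end, mean)`` triples with 1-based inclusive indices
    tiling ``[1, len(signal)]``.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ArgumentError("signal must be a non-empty 1-D array")
    if not np.isfinite(x).all():
        raise ArgumentError("signal contains non-finite values")
    if gamma < 0:
        raise ArgumentError("gamma must be >= 0")
    n = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i: int, j: int) -> float:  # residual SS of x[i..j-1] about its mean
        s = cs[j] - cs[i]
        return (cs2[j] - cs2[i]) - s * s / (j - i)

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = -gamma  # first segment carries no breakpoint penalty
    for j in range(1, n + 1):
        for i in range(j):
            c = best[i] + gamma + seg_cost(i, j)
            if c < best[j]:
                best[j] = c
                prev[j] = i
    bounds = []
    j = n
    while j > 0:
        i = prev[j]
        bounds.append((i, j))
        j = i
    bounds.reverse()
    return [(i + 1, j, float((cs[j] - cs[i]) / (j - i))) for i, j in bounds]


def call_segments(profile: SegmentedProfile, thresholds: CallThresholds | None = None
                  ) -> pd.DataFrame:
    """Per-segment discrete calls plus an LOH flag.

    Returns the segment table with added columns ``call`` (one of
    ``homdel/loss/neutral/gain``), ``amp``, ``high_amp`` and ``loh``.
    """
    thr = thresholds or CallThresholds()
    seg = profile.segments.copy()
    ploidy = profile.ploidy
    if thr.mode == "integer":
        tot = seg["total_cn"].to_numpy(dtype=float)
        if np.isnan(tot).any():
            raise DataError(f"integer mode requires total_cn for all segments "
                            f"({profile.sample_id})")
        gain = tot >= ploidy + thr.gain_margin
        loss = tot <= ploidy - thr.loss_margin
        amp = tot - ploidy >= thr.amp_copies
        high = tot - ploidy >= thr.high_amp_copies
        homdel = tot <= thr.homdel_total
    else:
        lr = seg["log_ratio"].to_numpy(dtype=float)
        if np.isnan(lr).any():
            raise DataError(f"log-ratio mode requires log_ratio for all segments "
                            f"({profile.sample_id})")
        gain = lr > thr.log_ratio_margin
        loss = lr < -thr.log_ratio_margin
        # copy counts unavailable: amplification classes approximated on the ratio scale
        amp = lr > np.log2((ploidy + thr.amp_copies) / ploidy)
        high = lr > np.log2((ploidy + thr.high_amp_copies) / ploidy)
        homdel = lr < np.log2(0.25 / ploidy) + 1e-9
    mino = seg["minor_cn"].to_numpy(dtype=float)
    tot = seg["total_cn"].to_numpy(dtype=float)
    loh = (mino == 0) & (np.nan_to_num(tot, nan=0.0) >= 1)
    call = np.where(homdel, "homdel", np.where(loss, "loss",
                    np.where(gain, "gain", "neutral")))
    seg["call"] = call
    seg["amp"] = amp
    seg["high_amp"] = high
    seg["loh"] = loh
    return seg


def genome_burden(calls: pd.DataFrame, sample_id: str = "",
                  loh_min: float = 24.0, loss_max: float = 6.0) -> BurdenSummary:
    """Percentage of the covered genome carrying each call class."""
    lengths = (calls["end"] - calls["start"] + 1).to_numpy(dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise DataError("calls cover zero genome length")
    call = calls["call"].to_numpy()
    gain = lengths[call == "gain"].sum()
    loss = lengths[np.isin(call, ["loss", "homdel"])].sum()
    loh = lengths[calls["loh"].to_numpy(dtype=bool)].sum()
    summary = BurdenSummary(
        sample_id=sample_id,
        pct_gain=100.0 * gain / total,
        pct_loss=100.0 * loss / total,
        pct_total_cna=100.0 * (gain + loss) / total,
        pct_loh=100.0 * loh / total,
    )
    summary.disproportionate_loh = detect_disproportionate_loh(summary, loh_min, loss_max)
    return summary


def detect_disproportionate_loh(burden: BurdenSummary, loh_min: float = 24.0,
                                loss_max: float = 6.0) -> bool:
    """High-LOH / low-loss rule: LOH over at least ``loh_min``% of the genome
    with copy-number losses below ``loss_max``%."""
    return bool(burden.pct_loh >= loh_min and burden.pct_loss < loss_max)


def burden_table(profiles: list[SegmentedProfile],
                 thresholds: CallThresholds | None = None,
                 loh_min: float = 24.0, loss_max: float = 6.0) -> pd.DataFrame:
    rows = []
    for p in profiles:
        b = genome_burden(call_segments(p, thresholds), p.sample_id, loh_min, loss_max)
        rows.append({"sample": b.sample_id, "pct_gain": b.pct_gain, "pct_loss": b.pct_loss,
                     "pct_total_cna": b.pct_total_cna, "pct_loh": b.pct_loh,
                     "disproportionate_loh": int(b.disproportionate_loh),
                     "ploidy": p.ploidy})
    return pd.DataFrame(rows)


def _discrete_from_continuous(values: np.ndarray, ploidy: float,
                              thr: CallThresholds) -> np.ndarray:
    call = np.full(values.shape, "neutral", dtype=object)
    call[values >= ploidy + thr.gain_margin] = "gain"
    call[values - ploidy >= thr.amp_copies] = "amp"
    call[values - ploidy >= thr.high_amp_copies] = "high_amp"
    call[values <= ploidy - thr.loss_margin] = "loss"
    call[values <= thr.homdel_total] = "homdel"
    call[np.isnan(values)] = "missing"
    return call


@dataclass
class GeneCNMatrix:
    """Gene x sample continuous copy number, discrete calls and LOH flags."""

    continuous: pd.DataFrame        # genes x samples, NaN where unmapped
    calls: pd.DataFrame             # genes x samples, strings from CALL_LEVELS or 'missing'
    loh: pd.DataFrame               # genes x samples, boolean
    ploidy: pd.Series               # per sample

    @property
    def genes(self) -> list[str]:
        return list(self.continuous.index)

    @property
    def samples(self) -> list[str]:
        return list(self.continuous.columns)

    def aberration_frequency(self, kind: str = "gain",
                             samples: list[str] | None = None) -> pd.Series:
        """Per-gene fraction of samples carrying a call; ``kind`` is ``gain``,
        ``loss`` or ``loss_or_loh``."""
        cols = samples if samples is not None else self.samples
        calls = self.calls[cols]
        if kind == "gain":
            hit = calls.isin(["gain", "amp", "high_amp"])
        elif kind == "loss":
            hit = calls.isin(["loss", "homdel"])
        elif kind == "loss_or_loh":
            hit = calls.isin(["loss", "homdel"]) | self.loh[cols]
        else:
            raise ArgumentError(f"unknown aberration kind {kind!r}")
        evaluable = calls != "missing"
        return hit.sum(axis=1) / evaluable.sum(axis=1)


def map_genes_to_cn(profiles: list[SegmentedProfile], gene_models: pd.DataFrame,
                    thresholds: CallThresholds | None = None,
                    rule: str = "weighted_mean") -> GeneCNMatrix:
    """Map per-segment copy number onto genes for every sample.

    ``weighted_mean`` (default): segment-length-weighted mean total copy
    number over the gene body.  ``majority``: the copy number of the segment
    with the largest overlap.  A gene with no overlapping segment is missing
    for that sample.  LOH is flagged when any overlapping segment carries it.
    """
    thr = thresholds or CallThresholds()
    if rule not in ("weighted_mean", "majority"):
        raise ArgumentError(f"unknown mapping rule {rule!r}")
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(gene_models.columns):
        raise DataError(f"gene models need columns {sorted(required)}")
    models = gene_models.reset_index(drop=True)
    genes = models["gene"].tolist()
    cont = pd.DataFrame(np.nan, index=genes, columns=[p.sample_id for p in profiles])
    loh = pd.DataFrame(False, index=genes, columns=cont.columns)
    for prof in profiles:
        col = np.full(len(models), np.nan)
        loh_col = np.zeros(len(models), dtype=bool)
        seg_by_chrom = {c: s.sort_values("start") for c, s in
                        prof.segments.groupby("chrom", sort=False)}
        for chrom, sub in models.groupby("chrom", sort=False):
            seg = seg_by_chrom.get(chrom)
            if seg is None:
                continue
            s_start = seg["start"].to_numpy()
            s_end = seg["end"].to_numpy()
            s_tot = seg["total_cn"].to_numpy(dtype=float)
            s_min = seg["minor_cn"].to_numpy(dtype=float)
            for gi, g_start, g_end in zip(sub.index, sub["start"], sub["end"]):
                lo = np.searchsorted(s_end, g_start)
                hi = np.searchsorted(s_start, g_end, side="right")
                if lo >= hi:
                    continue
                ov = (np.minimum(s_end[lo:hi], g_end)
                      - np.maximum(s_start[lo:hi], g_start) + 1).astype(float)
                keep = ov > 0
                if not keep.any():
                    continue
                ov, tot = ov[keep], s_tot[lo:hi][keep]
                if rule == "weighted_mean":
                    col[gi] = float(np.sum(ov * tot) / np.sum(ov))
                else:
                    col[gi] = float(tot[np.argmax(ov)])
                mino = s_min[lo:hi][keep]
                loh_col[gi] = bool(np.any((mino == 0) & (np.nan_to_num(tot) >= 1)))
        cont[prof.sample_id] = col
        loh[prof.sample_id] = loh_col
    calls = pd.DataFrame(index=genes, columns=cont.columns, dtype=object)
    ploidy = pd.Series({p.sample_id: p.ploidy for p in profiles})
    for p in profiles:
        calls[p.sample_id] = _discrete_from_continuous(
            cont[p.sample_id].to_numpy(dtype=float), p.ploidy, thr)
    return GeneCNMatrix(continuous=cont, calls=calls, loh=loh, ploidy=ploidy)
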