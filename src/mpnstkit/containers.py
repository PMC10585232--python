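"""In-memory containers shared by all analysis stages.

Copy-number profiles are held per sample as an ordered segment table
(chromosome, 1-based inclusive start/end, total and minor-allele copy
number, optional log-ratio) together with the sample's genome-wide ploidy;
gains and losses are always interpreted relative to that ploidy.  Expression
is a plain log2 genes x samples :class:`pandas.DataFrame` plus a
sample -> group annotation (``tumour`` / ``reference``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

SEGMENT_COLUMNS = ["chrom", "start", "end", "n_probes", "total_cn", "minor_cn", "log_ratio"]


@dataclass
class SegmentedProfile:
    """One sample's genome as ordered, non-overlapping segments."""

    sample_id: str
    segments: pd.DataFrame  # columns SEGMENT_COLUMNS
    ploidy: float

    def __post_init__(self) -> None:
        seg = self.segments
        missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
        if missing:
            raise DataError(f"segment table for {self.sample_id} lacks columns {missing}")
        if self.ploidy <= 0:
            raise DataError(f"ploidy must be positive, got {self.ploidy}")
        if (seg["start"] > seg["end"]).any():
            raise DataError(f"segment with start > end in {self.sample_id}")
        for chrom, sub in seg.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] <= s["end"].to_numpy()[:-1]).any():
                raise DataError(f"overlapping segments on {chrom} in {self.sample_id}")
        tot = seg["total_cn"].to_numpy(dtype=float)
        mino = seg["minor_cn"].to_numpy(dtype=float)
        ok = np.isnan(mino) | np.isnan(tot) | (mino <= tot + 1e-9)
        if not ok.all():
            raise DataError(f"minor_cn exceeds total_cn in {self.sample_id}")

    @property
    def covered_length(self) -> int:
        return int((self.segments["end"] - self.segments["start"] + 1).sum())


@dataclass
class ExpressionMatrix:
    """log2 expression values, genes as rows, samples as columns."""

    values: pd.DataFrame
    groups: pd.Series  # sample -> 'tumour' | 'reference'

    def __post_init__(self) -> None:
        if self.values.empty:
            raise DataError("expression matrix is empty")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise DataError("every expression sample needs a group annotation")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def tumour_samples(self) -> list[str]:
        return [s for s in self.samples if self.groups[s] == "tumour"]

    def reference_samples(self) -> list[str]:
        return [s for s in self.samples if self.groups[s] == "reference"]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)], self.groups.copy())


@dataclass
class CohortTruth:
    """Latent state of a synthetic cohort, used by recovery tests."""

    samples: pd.DataFrame  # sample, subtype, ploidy, disproportionate_loh, burden covariates
    immune_genes: list[str] = field(default_factory=list)
    dosage_genes: list[str] = field(default_factory=list)


def infer_ploidy(segments: pd.DataFrame) -> float:
    """Length-weighted median total copy number, rounded to an integer.

    The segment interchange format carries no ploidy column, so when none is
    supplied the genome-wide baseline is taken as the rounded weighted median
    of the total copy number (the neutral state dominates any realistic
    profile).
    """
    tot = segments["total_cn"].to_numpy(dtype=float)
    w = (segments["end"] - segments["start"] + 1).to_numpy(dtype=float)
    keep = np.isfinite(tot)
    if not keep.any():
        raise DataError("cannot infer ploidy: no total_cn values")
    order = np.argsort(tot[keep])
    tot_s, w_s = tot[keep][order], w[keep][order]
    cum = np.cumsum(w_s)
    med = tot_s[np.searchsorted(cum, 0.5 * cum[-1])]
    return float(max(1.0, round(med)))
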