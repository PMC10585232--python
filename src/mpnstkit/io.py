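"""Readers and writers for the tab-delimited interchange formats.

All files are UTF-8, tab-delimited, with a header row:

* segments: ``sample  chrom  start  end  n_probes  total_cn  minor_cn  log_ratio``
* expression: first column ``gene``, one column per sample
* gene models: ``gene  chrom  start  end`` (optional ``planted`` column)
* gene sets: GMT (set name, description, then tab-separated members)
* clinical: ``sample  group  time  event`` plus free covariate columns

Coordinates are 1-based inclusive.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SEGMENT_COLUMNS, SegmentedProfile, ExpressionMatrix, infer_ploidy
from .errors import DataError, ParseError

SEG_HEADER = ["sample"] + SEGMENT_COLUMNS


def read_segments(path, ploidy_by_sample: dict[str, float] | None = None) -> list[SegmentedProfile]:
    """Parse a SEG-like TSV into per-sample profiles.

    ``ploidy_by_sample`` supplies genome-wide ploidy per sample; samples
    missing from it fall back to :func:`infer_ploidy`.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SEG_HEADER:
            raise ParseError(f"unexpected segment header {header!r}", path, 1)
        rows = []
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(SEG_HEADER):
                raise ParseError(
                    f"expected {len(SEG_HEADER)} fields, got {len(parts)}: {line!r}",
                    path, line_no,
                )
            try:
                rows.append({
                    "sample": parts[0],
                    "chrom": parts[1],
                    "start": int(parts[2]),
                    "end": int(parts[3]),
                    "n_probes": int(parts[4]),
                    "total_cn": float(parts[5]) if parts[5] not in ("", "NA") else np.nan,
                    "minor_cn": float(parts[6]) if parts[6] not in ("", "NA") else np.nan,
                    "log_ratio": float(parts[7]) if parts[7] not in ("", "NA") else np.nan,
                })
            except ValueError as exc:
                raise ParseError(f"could not parse segment line: {exc}", path, line_no) from exc
    if not rows:
        raise ParseError("segment file contains no data rows", path)
    table = pd.DataFrame(rows)
    profiles = []
    for sample, sub in table.groupby("sample", sort=False):
        seg = sub[SEGMENT_COLUMNS].reset_index(drop=True)
        if ploidy_by_sample is not None and sample in ploidy_by_sample:
            ploidy = float(ploidy_by_sample[sample])
        else:
            ploidy = infer_ploidy(seg)
        profiles.append(SegmentedProfile(sample_id=str(sample), segments=seg, ploidy=ploidy))
    return profiles


def write_segments(profiles: list[SegmentedProfile], path) -> None:
    frames = []
    for p in profiles:
        seg = p.segments.copy()
        seg.insert(0, "sample", p.sample_id)
        frames.append(seg)
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_expression(path, clinical: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a log2 expression TSV; groups come from ``clinical`` or default to tumour."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = "gene"
    if clinical is not None:
        groups = clinical.set_index("sample")["group"].reindex(values.columns)
        if groups.isna().any():
            missing = list(values.columns[groups.isna()])
            raise DataError(f"samples missing from clinical table: {missing[:5]}")
    else:
        groups = pd.Series("tumour", index=values.columns)
    return ExpressionMatrix(values=values, groups=groups)


def write_expression(expr: ExpressionMatrix, path) -> None:
    out = expr.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_gene_models(path) -> pd.DataFrame:
    models = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start", "end"}
    if not required.issubset(models.columns):
        raise ParseError(f"gene model table needs columns {sorted(required)}", path)
    if (models["start"] > models["end"]).any():
        raise DataError("gene model with start > end")
    return models


def write_gene_models(models: pd.DataFrame, path) -> None:
    models.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError("GMT line needs name, description, >=1 member", path, line_no)
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ParseError("GMT file contains no gene sets", path)
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "synthetic") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description] + list(members)) + "\n")


def read_clinical(path) -> pd.DataFrame:
    clinical = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "time", "event"}
    if not required.issubset(clinical.columns):
        raise ParseError(f"clinical table needs columns {sorted(required)}", path)
    return clinical


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line (cancer-critical and drug-target lists)."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def ensure_writable_dir(directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if not os.access(directory, os.W_OK):
        raise OSError(f"directory {directory} is not writable")
    return directory
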