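"""Synthetic cohort generator.

Emulates the statistical structure of a tumour cohort profiled on two
levels: allele-specific DNA copy number (segmented profiles per sample) and
log2 gene expression, together with a small synthetic genome, gene-set
collection and clinical/survival table.

The latent model has two transcriptomic tumour subtypes:

* ``immune_active`` (default 44% of tumours): an immune expression program
  is shifted up by ``immune_effect`` log2 units relative to the deficient
  subtype, independent of copy number, and matches the benign reference
  samples.  Copy-number event rates are low.
* ``immune_deficient`` (56%): immune program down, higher gain/loss/LOH
  event rates, triploid genomes with probability ``frac_triploid_deficient``.

A proliferation program is copy-number driven: for each planted dosage gene
``expr = baseline + dosage_slope * log2(CN / ploidy) + noise``, so its
expression tracks the gene's dosage relative to the sample's genome-wide
baseline.  A fraction of tumours (default 15%, drawn from the deficient
subtype) carries *disproportionate LOH*: copy-neutral LOH (minor allele 0 at
ploidy total) over a large genome fraction with almost no physical loss.
Benign reference samples are diploid and copy-neutral apart from a rare
focal homozygous deletion.

Survival times are exponential under a proportional-hazards model with
per-sample hazard ``baseline * hr_subtype^[deficient] *
hr_per_burden_unit^(pct_total_cna)``, administratively censored at five
time-units with additional uniform dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import SEGMENT_COLUMNS, CohortTruth, ExpressionMatrix, SegmentedProfile
from .errors import ConfigurationError, DataError
from . import io as mio

ACTIVE = "immune_active"
DEFICIENT = "immune_deficient"


@dataclass
class CohortConfig:
    """Parameters of the generative model; defaults are the study conditions."""

    n_tumours: int = 64
    n_references: int = 15
    subtype_fractions: tuple[float, float] = (0.44, 0.56)  # (active, deficient)
    n_genes: int = 1000
    n_chromosomes: int = 5
    chromosome_length: int = 10_000_000
    immune_set_size: int = 80
    proliferation_set_size: int = 80
    n_background_sets: int = 8
    background_set_size: int = 50
    immune_effect: float = 1.5          # log2 shift, active minus deficient
    dosage_slope: float = 1.0           # log2 expr per log2(CN/ploidy)
    noise_sd: float = 0.5               # log2 units
    frac_triploid_deficient: float = 0.35
    frac_disproportionate_loh: float = 0.15
    reference_homdel_rate: float = 0.14
    survival_baseline_hazard: float = 0.12
    hr_subtype: float = 4.0
    hr_per_burden_unit: float = 1.03    # per percentage point of total CNA
    dropout_rate: float = 0.10
    mean_segment_length: float = 1_500_000.0
    # per-subtype per-segment event probabilities (gain, loss, copy-neutral LOH)
    event_rates_active: tuple[float, float, float] = (0.08, 0.05, 0.02)
    event_rates_deficient: tuple[float, float, float] = (0.22, 0.13, 0.04)
    # recurrently gained distal region per chromosome: genome fraction and
    # per-sample gain probability by subtype (hosts the proliferation program)
    hotspot_fraction: float = 0.3
    recurrent_gain_rate_active: float = 0.12
    recurrent_gain_rate_deficient: float = 0.45
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.subtype_fractions) - 1.0) > 1e-9:
            raise ConfigurationError("subtype fractions must sum to 1")
        for name in ("n_tumours", "n_references", "n_genes", "n_chromosomes",
                     "chromosome_length", "immune_set_size", "proliferation_set_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("frac_triploid_deficient", "frac_disproportionate_loh",
                     "reference_homdel_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("survival_baseline_hazard", "hr_subtype", "hr_per_burden_unit"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.noise_sd < 0 or self.dosage_slope < 0:
            raise ConfigurationError("noise_sd and dosage_slope must be non-negative")
        for rates in (self.event_rates_active, self.event_rates_deficient):
            if any(r < 0 for r in rates) or sum(rates) > 1:
                raise ConfigurationError("event rates must be non-negative and sum to <= 1")
        if self.immune_set_size + self.proliferation_set_size > self.n_genes:
            raise ConfigurationError("planted programs exceed the gene count")


@dataclass
class SyntheticCohort:
    config: CohortConfig
    segmented_profiles: list[SegmentedProfile]
    expression: ExpressionMatrix
    gene_models: pd.DataFrame
    gene_sets: dict[str, list[str]]
    clinical: pd.DataFrame
    truth: CohortTruth

    @property
    def chromosome_lengths(self) -> dict[str, int]:
        cfg = self.config
        return {f"chr{i + 1}": cfg.chromosome_length for i in range(cfg.n_chromosomes)}


def _segment_breaks(rng, length: float, mean_len: float) -> np.ndarray:
    """Ends (1-based inclusive) of an exponential-length segmentation tiling [1, length]."""
    ends = []
    pos = 0
    while pos < length:
        pos = min(length, pos + max(50_000, int(rng.exponential(mean_len))))
        ends.append(pos)
    return np.asarray(ends, dtype=int)


def _simulate_profile(rng, sample_id: str, cfg: CohortConfig, ploidy: int,
                      rates: tuple[float, float, float], p_recurrent: float,
                      disproportionate: bool, reference: bool) -> SegmentedProfile:
    p_gain, p_loss, p_cnloh = rates
    if disproportionate:
        # copy-neutral LOH planted below to a target coverage; physical losses
        # suppressed so the high-LOH / low-loss profile holds by construction
        p_cnloh = 0.0
        p_loss = 0.0
        p_gain = 0.05
    hotspot_start = (1.0 - cfg.hotspot_fraction) * cfg.chromosome_length
    rows = []
    for c in range(cfg.n_chromosomes):
        chrom = f"chr{c + 1}"
        ends = _segment_breaks(rng, cfg.chromosome_length, cfg.mean_segment_length)
        starts = np.concatenate([[1], ends[:-1] + 1])
        # recurrent distal gain (+1 or +2 over ploidy) hits whole hotspots,
        # mirroring arm-level gains shared across tumours
        hot = (not reference) and rng.random() < p_recurrent
        hot_extra = int(rng.choice([1, 2], p=[0.65, 0.35]))
        for start, end in zip(starts, ends):
            total, minor = float(ploidy), float(ploidy // 2)
            in_hotspot = (start + end) / 2.0 >= hotspot_start
            if not reference:
                u = rng.random()
                if u < p_gain:
                    extra = int(rng.choice([1, 2, int(rng.integers(5, 13))], p=[0.6, 0.3, 0.1]))
                    total = float(ploidy + extra)
                    minor = float(max(1, ploidy // 2))
                elif u < p_gain + p_loss:
                    drop = int(rng.choice([1, 2], p=[0.8, 0.2]))
                    total = float(max(0, ploidy - drop))
                    minor = 0.0
                elif u < p_gain + p_loss + p_cnloh:
                    total, minor = float(ploidy), 0.0
                elif hot and in_hotspot:
                    total = float(ploidy + hot_extra)
                    minor = float(max(1, ploidy // 2))
            lr = float(np.log2(max(total, 0.25) / ploidy))
            rows.append((chrom, int(start), int(end), int((end - start + 1) // 10_000),
                         total, minor, lr))
    seg = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    if disproportionate:
        # flip neutral segments to copy-neutral LOH until the drawn genome
        # fraction is covered; guarantees LOH >= 30% with losses < ~2%
        target = rng.uniform(0.30, 0.70)
        lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
        genome = lengths.sum()
        covered = lengths[(seg["minor_cn"] == 0) & (seg["total_cn"] >= 1)].sum()
        neutral_idx = seg.index[(seg["total_cn"] == ploidy) & (seg["minor_cn"] > 0)]
        for i in rng.permutation(neutral_idx.to_numpy()):
            if covered / genome >= target:
                break
            seg.loc[i, "minor_cn"] = 0.0
            covered += lengths[i]
    if reference and rng.random() < cfg.reference_homdel_rate:
        # focal homozygous deletion inside one existing segment
        i = int(rng.integers(len(seg)))
        row = seg.iloc[i]
        width = 200_000
        if row["end"] - row["start"] + 1 > 3 * width:
            s0 = int(row["start"] + width)
            pieces = pd.DataFrame([
                (row["chrom"], row["start"], s0 - 1, (s0 - row["start"]) // 10_000,
                 row["total_cn"], row["minor_cn"], row["log_ratio"]),
                (row["chrom"], s0, s0 + width - 1, width // 10_000, 0.0, 0.0,
                 float(np.log2(0.25 / ploidy))),
                (row["chrom"], s0 + width, row["end"], (row["end"] - s0 - width + 1) // 10_000,
                 row["total_cn"], row["minor_cn"], row["log_ratio"]),
            ], columns=SEGMENT_COLUMNS)
            seg = pd.concat([seg.iloc[:i], pieces, seg.iloc[i + 1:]], ignore_index=True)
    return SegmentedProfile(sample_id=sample_id, segments=seg, ploidy=float(ploidy))


def _gene_cn(profile: SegmentedProfile, models: pd.DataFrame) -> np.ndarray:
    """Total copy number of the segment covering each (point-like) gene midpoint."""
    cn = np.full(len(models), np.nan)
    for chrom, sub in models.groupby("chrom", sort=False):
        seg = profile.segments[profile.segments["chrom"] == chrom].sort_values("start")
        if seg.empty:
            continue
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
        idx = np.searchsorted(seg["end"].to_numpy(), mids)
        idx = np.clip(idx, 0, len(seg) - 1)
        cn[sub.index.to_numpy()] = seg["total_cn"].to_numpy()[idx]
    return cn


def _burden_fractions(profile: SegmentedProfile) -> tuple[float, float, float]:
    """(gain, loss, LOH) fractions of the covered genome, relative to ploidy."""
    seg = profile.segments
    lengths = (seg["end"] - seg["start"] + 1).to_numpy(dtype=float)
    total = lengths.sum()
    tot = seg["total_cn"].to_numpy(dtype=float)
    mino = seg["minor_cn"].to_numpy(dtype=float)
    gain = lengths[tot >= profile.ploidy + 1].sum() / total
    loss = lengths[tot <= profile.ploidy - 1].sum() / total
    loh = lengths[(mino == 0) & (tot >= 1)].sum() / total
    return float(gain), float(loss), float(loh)


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Draw one cohort from the generative model; deterministic given ``config.seed``."""
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- genome and planted programs -------------------------------------
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    chroms, starts = [], []
    for i in range(cfg.n_genes):
        c = i // per_chrom
        j = i % per_chrom
        spacing = cfg.chromosome_length // (per_chrom + 1)
        chroms.append(f"chr{c + 1}")
        starts.append((j + 1) * spacing)
    models = pd.DataFrame({
        "gene": genes, "chrom": chroms,
        "start": starts, "end": [s + 9_999 for s in starts],
    })
    # the proliferation (dosage) program lives in the recurrently gained
    # distal hotspots; the immune program lies outside them
    hotspot_start = (1.0 - cfg.hotspot_fraction) * cfg.chromosome_length
    mid = (models["start"] + models["end"]) / 2.0
    hot_idx = models.index[mid >= hotspot_start].to_numpy()
    cold_idx = models.index[mid < hotspot_start].to_numpy()
    if len(hot_idx) < cfg.proliferation_set_size or len(cold_idx) < cfg.immune_set_size:
        raise ConfigurationError("gene count too small for the planted programs")
    dosage_rows_pick = rng.choice(hot_idx, size=cfg.proliferation_set_size, replace=False)
    immune_rows_pick = rng.choice(cold_idx, size=cfg.immune_set_size, replace=False)
    immune_genes = [genes[i] for i in sorted(immune_rows_pick)]
    dosage_genes = [genes[i] for i in sorted(dosage_rows_pick)]
    models["planted"] = "none"
    models.loc[models["gene"].isin(immune_genes), "planted"] = "immune"
    models.loc[models["gene"].isin(dosage_genes), "planted"] = "dosage"

    gene_sets = {"IMMUNE_PROGRAM": immune_genes, "PROLIFERATION_PROGRAM": dosage_genes}
    for b in range(cfg.n_background_sets):
        members = rng.choice(genes, size=min(cfg.background_set_size, cfg.n_genes),
                             replace=False)
        gene_sets[f"BACKGROUND_{b + 1:02d}"] = sorted(members.tolist())

    # --- samples, subtypes, ploidy ---------------------------------------
    tumour_ids = [f"T{i + 1:03d}" for i in range(cfg.n_tumours)]
    ref_ids = [f"R{i + 1:03d}" for i in range(cfg.n_references)]
    n_active = int(round(cfg.subtype_fractions[0] * cfg.n_tumours))
    subtype = np.array([ACTIVE] * n_active + [DEFICIENT] * (cfg.n_tumours - n_active))
    rng.shuffle(subtype)
    deficient_idx = np.flatnonzero(subtype == DEFICIENT)
    n_disp = int(round(cfg.frac_disproportionate_loh * cfg.n_tumours))
    n_disp = min(n_disp, len(deficient_idx))
    disp_idx = set(rng.choice(deficient_idx, size=n_disp, replace=False).tolist())

    profiles: list[SegmentedProfile] = []
    ploidies, disp_flags = [], []
    for i, sid in enumerate(tumour_ids):
        if subtype[i] == DEFICIENT:
            ploidy = 3 if rng.random() < cfg.frac_triploid_deficient else 2
            rates = cfg.event_rates_deficient
            p_rec = cfg.recurrent_gain_rate_deficient
        else:
            ploidy = 2
            rates = cfg.event_rates_active
            p_rec = cfg.recurrent_gain_rate_active
        disp = i in disp_idx
        profiles.append(_simulate_profile(rng, sid, cfg, ploidy, rates, p_rec, disp,
                                          reference=False))
        ploidies.append(ploidy)
        disp_flags.append(disp)
    for sid in ref_ids:
        profiles.append(_simulate_profile(rng, sid, cfg, 2, (0, 0, 0), 0.0, False,
                                          reference=True))

    # --- expression --------------------------------------------------------
    all_ids = tumour_ids + ref_ids
    baseline = rng.normal(7.0, 1.0, size=cfg.n_genes)
    expr = np.tile(baseline[:, None], (1, len(all_ids)))
    immune_rows = models.index[models["planted"] == "immune"].to_numpy()
    dosage_rows = models.index[models["planted"] == "dosage"].to_numpy()
    for j, prof in enumerate(profiles):
        is_tumour = j < cfg.n_tumours
        high_immune = (not is_tumour) or subtype[j] == ACTIVE
        if high_immune:
            expr[immune_rows, j] += cfg.immune_effect
        cn = _gene_cn(prof, models)
        dose = np.log2(np.maximum(cn[dosage_rows], 0.25) / prof.ploidy)
        expr[dosage_rows, j] += cfg.dosage_slope * np.nan_to_num(dose)
    expr += rng.normal(0.0, cfg.noise_sd, size=expr.shape)
    expression = ExpressionMatrix(
        values=pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=all_ids),
        groups=pd.Series(["tumour"] * cfg.n_tumours + ["reference"] * cfg.n_references,
                         index=all_ids),
    )

    # --- survival and clinical covariates ----------------------------------
    rows = []
    for i, sid in enumerate(tumour_ids):
        gain, loss, loh = _burden_fractions(profiles[i])
        burden_pct = 100.0 * (gain + loss)
        log_hr = (np.log(cfg.hr_subtype) * (subtype[i] == DEFICIENT)
                  + np.log(cfg.hr_per_burden_unit) * burden_pct)
        hazard = cfg.survival_baseline_hazard * np.exp(log_hr)
        t_event = rng.exponential(1.0 / hazard)
        c = 5.0 if rng.random() >= cfg.dropout_rate else rng.uniform(0.0, 5.0)
        time = min(t_event, c)
        rows.append({
            "sample": sid, "group": "tumour",
            "time": max(time, 1e-3), "event": int(t_event <= c),
            "sex": ["female", "male"][int(rng.random() < 0.5)],
            "nf1": int(rng.random() < 0.5),
            "age": float(np.round(rng.normal(36.0, 12.0), 1)),
            "pct_gain_true": 100.0 * gain, "pct_loss_true": 100.0 * loss,
            "pct_loh_true": 100.0 * loh,
        })
    for sid in ref_ids:
        rows.append({"sample": sid, "group": "reference", "time": np.nan, "event": 0,
                     "sex": ["female", "male"][int(rng.random() < 0.5)],
                     "nf1": 0, "age": float(np.round(rng.normal(36.0, 12.0), 1)),
                     "pct_gain_true": 0.0, "pct_loss_true": 0.0, "pct_loh_true": 0.0})
    clinical = pd.DataFrame(rows)

    truth_samples = pd.DataFrame({
        "sample": tumour_ids,
        "subtype": subtype,
        "ploidy": ploidies,
        "disproportionate_loh": [int(f) for f in disp_flags],
    })
    truth = CohortTruth(samples=truth_samples, immune_genes=immune_genes,
                        dosage_genes=dosage_genes)
    return SyntheticCohort(config=cfg, segmented_profiles=profiles, expression=expression,
                           gene_models=models, gene_sets=gene_sets, clinical=clinical,
                           truth=truth)


def write_cohort(cohort: SyntheticCohort, directory) -> dict[str, Path]:
    """Write the six-file cohort bundle; returns the file manifest."""
    if not cohort.segmented_profiles or not cohort.expression.samples:
        raise DataError("refusing to write an empty cohort")
    directory = mio.ensure_writable_dir(directory)
    manifest = {
        "segments": directory / "segments.tsv",
        "expression": directory / "expression.tsv",
        "gene_models": directory / "gene_models.tsv",
        "gene_sets": directory / "gene_sets.gmt",
        "clinical": directory / "clinical.tsv",
        "truth": directory / "truth.tsv",
    }
    mio.write_segments(cohort.segmented_profiles, manifest["segments"])
    mio.write_expression(cohort.expression, manifest["expression"])
    mio.write_gene_models(cohort.gene_models, manifest["gene_models"])
    mio.write_gmt(cohort.gene_sets, manifest["gene_sets"])
    mio.write_table(cohort.clinical, manifest["clinical"])
    mio.write_table(cohort.truth.samples, manifest["truth"])
    for name, path in manifest.items():
        if path.stat().st_size == 0:
            raise DataError(f"wrote empty {name} file")
    return manifest


def read_cohort(directory, config: CohortConfig | None = None) -> SyntheticCohort:
    """Re-assemble a cohort bundle written by :func:`write_cohort`."""
    directory = Path(directory)
    truth_samples = pd.read_csv(directory / "truth.tsv", sep="\t")
    ploidy = dict(zip(truth_samples["sample"], truth_samples["ploidy"].astype(float)))
    profiles = mio.read_segments(directory / "segments.tsv", ploidy_by_sample=ploidy)
    clinical = mio.read_clinical(directory / "clinical.tsv")
    expression = mio.read_expression(directory / "expression.tsv", clinical=clinical)
    models = mio.read_gene_models(directory / "gene_models.tsv")
    gene_sets = mio.read_gmt(directory / "gene_sets.gmt")
    if "planted" in models.columns:
        immune = models.loc[models["planted"] == "immune", "gene"].tolist()
        dosage = models.loc[models["planted"] == "dosage", "gene"].tolist()
    else:
        immune, dosage = [], []
    truth = CohortTruth(samples=truth_samples, immune_genes=immune, dosage_genes=dosage)
    return SyntheticCohort(config=config or CohortConfig(), segmented_profiles=profiles,
                           expression=expression, gene_models=models, gene_sets=gene_sets,
                           clinical=clinical, truth=truth)


def config_to_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["subtype_fractions"] = list(d["subtype_fractions"])
    d["event_rates_active"] = list(d["event_rates_active"])
    d["event_rates_deficient"] = list(d["event_rates_deficient"])
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    for key in ("subtype_fractions", "event_rates_active", "event_rates_deficient"):
        if key in d:
            d[key] = tuple(d[key])
    return CohortConfig(**d)
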