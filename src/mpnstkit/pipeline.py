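"""End-to-end orchestration of the analysis stages.

Stage order mirrors the analysis flow: simulate (or load) -> copy-number
calls and burden -> gene-level copy number -> transcriptomic subtyping ->
gene-set enrichment -> copy-number/expression concurrency -> survival.
Every stage is a pure function of its inputs and the seed, so re-running
with the same configuration reproduces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .clinstats import apply_administrative_censoring, combined_strata, cox_ph, \
    dichotomize_burden, km_curve
from .containers import ExpressionMatrix
from .copynumber import CallThresholds, burden_table, map_genes_to_cn
from .enrichment import camera_table, differential_expression, ssgsva
from .errors import ConfigurationError, MPNSTKitError
from .integration import IntegrationConfig, call_concurrency, concurrent_genes, \
    geneset_concurrency_enrichment, intersect_candidates, nominate_loss_targets
from .subtypes import DEFICIENT, ACTIVE, SubtypeConfig, name_subtypes, nmf_consensus, \
    select_variable_genes
from .synthetic import CohortConfig, config_from_dict, config_to_dict, \
    generate_cohort, read_cohort, write_cohort

log = logging.getLogger("mpnstkit")


@dataclasses.dataclass
class PipelineConfig:
    outdir: str = "results/run"
    seed: int = 0
    simulate: CohortConfig | None = None
    input_dir: str | None = None
    thresholds: CallThresholds = dataclasses.field(default_factory=CallThresholds)
    subtype: SubtypeConfig = dataclasses.field(default_factory=SubtypeConfig)
    integration: IntegrationConfig = dataclasses.field(default_factory=IntegrationConfig)
    survival_horizon: float = 5.0
    loh_min: float = 24.0
    loss_max: float = 6.0
    gain_freq_min: float = 0.20
    target_freq_diff_min: float = 0.40
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ConfigurationError(
                "exactly one of a simulate block or an input directory is required")

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir, "seed": self.seed,
            "input_dir": self.input_dir,
            "simulate": config_to_dict(self.simulate) if self.simulate else None,
            "thresholds": dataclasses.asdict(self.thresholds),
            "subtype": dataclasses.asdict(self.subtype),
            "integration": dataclasses.asdict(self.integration),
            "survival_horizon": self.survival_horizon,
            "loh_min": self.loh_min, "loss_max": self.loss_max,
            "gain_freq_min": self.gain_freq_min,
            "target_freq_diff_min": self.target_freq_diff_min,
            "log_level": self.log_level,
        }
        return d


def config_from_yaml(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_mapping(raw)


def config_from_mapping(raw: dict) -> PipelineConfig:
    kwargs = dict(raw)
    if kwargs.get("simulate"):
        kwargs["simulate"] = config_from_dict(kwargs["simulate"])
    if kwargs.get("thresholds"):
        kwargs["thresholds"] = CallThresholds(**kwargs["thresholds"])
    if kwargs.get("subtype"):
        kwargs["subtype"] = SubtypeConfig(**kwargs["subtype"])
    if kwargs.get("integration"):
        kwargs["integration"] = IntegrationConfig(**kwargs["integration"])
    return PipelineConfig(**kwargs)


def template_config() -> str:
    """A YAML template with every default made explicit."""
    cfg = PipelineConfig(simulate=CohortConfig())
    return yaml.safe_dump(cfg.to_dict(), sort_keys=False)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except MPNSTKitError as exc:
                raise MPNSTKitError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and return the manifest of written outputs."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = mio.ensure_writable_dir(config.outdir)
    manifest: dict[str, Path] = {}

    if config.simulate is not None:
        cfg = dataclasses.replace(config.simulate, seed=config.seed)
        cohort = _stage("simulate")(generate_cohort)(cfg)
        write_cohort(cohort, outdir / "cohort")
    else:
        cohort = _stage("load")(read_cohort)(config.input_dir)
    log.info("thresholds: %s", dataclasses.asdict(config.thresholds))

    # --- copy-number burden ------------------------------------------------
    tumour_profiles = [p for p in cohort.segmented_profiles
                       if p.sample_id in set(cohort.truth.samples["sample"])]
    burdens = _stage("burden")(burden_table)(
        tumour_profiles, config.thresholds, config.loh_min, config.loss_max)
    manifest["burden"] = outdir / "burden.tsv"
    mio.write_table(burdens, manifest["burden"])

    gene_cn = _stage("gene_cn")(map_genes_to_cn)(
        cohort.segmented_profiles, cohort.gene_models, config.thresholds)

    # --- subtype discovery -------------------------------------------------
    expr = cohort.expression
    tumours = expr.tumour_samples()
    sub_cfg = dataclasses.replace(config.subtype, seed=config.seed)
    variable = select_variable_genes(expr, sub_cfg.variance_threshold, samples=tumours)
    assignment = _stage("subtype")(nmf_consensus)(
        expr.subset_genes(variable), sub_cfg, samples=tumours)
    immune_sets = {k: v for k, v in cohort.gene_sets.items() if "IMMUNE" in k.upper()}
    if not immune_sets:
        immune_sets = dict(list(cohort.gene_sets.items())[:1])
    assignment = name_subtypes(assignment, expr, immune_sets)
    labels = assignment.named_labels()
    subtype_out = pd.DataFrame({"sample": labels.index, "subtype": labels.to_numpy(),
                                "cluster": assignment.labels.to_numpy()})
    manifest["subtypes"] = outdir / "subtypes.tsv"
    mio.write_table(subtype_out, manifest["subtypes"])
    manifest["consensus"] = outdir / "consensus.tsv"
    assignment.consensus.to_csv(manifest["consensus"], sep="\t")

    deficient = list(labels.index[labels == DEFICIENT])
    active = list(labels.index[labels == ACTIVE])

    # --- enrichment --------------------------------------------------------
    de = _stage("differential_expression")(differential_expression)(
        expr, deficient, active)
    manifest["de_subtypes"] = outdir / "de_deficient_vs_active.tsv"
    mio.write_table(de.table.reset_index(names="gene"), manifest["de_subtypes"])
    camera = _stage("camera")(camera_table)(expr, deficient, active, cohort.gene_sets)
    manifest["camera"] = outdir / "camera_deficient_vs_active.tsv"
    mio.write_table(camera, manifest["camera"])
    scores = _stage("ssgsva")(ssgsva)(expr, cohort.gene_sets)
    manifest["ssgsva"] = outdir / "ssgsva_scores.tsv"
    scores.to_csv(manifest["ssgsva"], sep="\t")

    # --- concurrency integration ------------------------------------------
    calls = _stage("concurrency")(call_concurrency)(
        gene_cn, expr, config.integration, samples=tumours)
    manifest["concurrency"] = outdir / "concurrency_calls.tsv"
    mio.write_table(calls, manifest["concurrency"])
    enrich = _stage("concurrency_sets")(geneset_concurrency_enrichment)(
        calls, cohort.gene_sets)
    manifest["concurrency_sets"] = outdir / "concurrency_set_enrichment.tsv"
    mio.write_table(enrich, manifest["concurrency_sets"])
    gain_freq = gene_cn.aberration_frequency("gain", samples=[
        p.sample_id for p in tumour_profiles])
    candidates = intersect_candidates(
        de.significant(direction="up"), concurrent_genes(calls, "gain_up"),
        gain_freq, config.gain_freq_min)
    manifest["candidates"] = outdir / "candidate_genes.tsv"
    mio.write_table(pd.DataFrame({"gene": candidates["candidates"]}),
                    manifest["candidates"])

    # --- survival ----------------------------------------------------------
    survival = apply_administrative_censoring(
        cohort.clinical[cohort.clinical["group"] == "tumour"], config.survival_horizon)
    surv_labeled = survival.merge(subtype_out[["sample", "subtype"]], on="sample")
    surv_labeled["deficient"] = (surv_labeled["subtype"] == DEFICIENT).astype(float)
    cox = _stage("cox_subtype")(cox_ph)(surv_labeled, ["deficient"])
    _, km_pairs = km_curve(surv_labeled, "subtype")
    burden_idx = burdens.set_index("sample")
    strata_report = {}
    labels_by_kind = {}
    for kind in ("pct_gain", "pct_loss", "pct_loh"):
        try:
            labels_by_kind[kind] = dichotomize_burden(
                burden_idx[kind], survival)["labels"]
        except MPNSTKitError as exc:
            log.warning("dichotomization for %s failed: %s", kind, exc)
    if {"pct_loss", "pct_loh"} <= set(labels_by_kind):
        strata = combined_strata(
            labels_by_kind["pct_loss"], labels_by_kind["pct_loh"], survival,
            gain_labels=labels_by_kind.get("pct_gain"),
            subtype_labels=labels.copy())
        strata_report = {"strata_sizes": strata["strata_sizes"]}
    surv_summary = cox.table.reset_index(names="covariate")
    manifest["survival"] = outdir / "survival_subtype_cox.tsv"
    mio.write_table(surv_summary, manifest["survival"])
    manifest["survival_pairs"] = outdir / "survival_subtype_km_pairs.tsv"
    mio.write_table(km_pairs, manifest["survival_pairs"])

    # --- nomination (needs strata + survival) ------------------------------
    if "pct_loh" in labels_by_kind and deficient:
        lossloh = burden_idx["pct_loss"] + burden_idx["pct_loh"]
        try:
            split = dichotomize_burden(
                lossloh.rename("burden"),
                survival[survival["sample"].isin(deficient)])
            lab = split["labels"]
            high = [s for s in deficient if lab.get(s) == "high"]
            low = [s for s in deficient if lab.get(s) == "low"]
            if len(high) >= 3 and len(low) >= 3:
                cancer_list = cohort.gene_sets.get(
                    "CANCER_CRITICAL", cohort.truth.dosage_genes + cohort.truth.immune_genes)
                noms = _stage("nominate")(nominate_loss_targets)(
                    high, low, gene_cn, expr, survival, cancer_list, calls,
                    config.target_freq_diff_min)
                manifest["nominations"] = outdir / "loss_target_nominations.tsv"
                mio.write_table(noms, manifest["nominations"])
        except MPNSTKitError as exc:
            log.warning("target nomination skipped: %s", exc)

    meta = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest(),
        "config": config.to_dict(),
        "n_tumours": len(tumours),
        "subtype_sizes": {DEFICIENT: len(deficient), ACTIVE: len(active)},
        "cox_subtype_hr": float(cox.hr("deficient")),
        "strata": strata_report,
        "candidate_count": len(candidates["candidates"]),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    manifest["metadata"] = outdir / "run_metadata.json"
    with open(manifest["metadata"], "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return manifest
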