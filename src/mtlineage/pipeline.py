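"""End-to-end orchestration: simulate -> call -> filter -> annotate -> clonality.

One threshold set is applied to every lesion of every patient (batch
semantics: per-sample overrides are disallowed so results stay comparable
across a cohort).  The output layout is deterministic and, for a fixed
config and seed, byte-identical across runs; the run log is the only
non-deterministic artifact (it carries timings) and is excluded from that
contract.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .annotate import annotate_polymorphisms, load_polymorphism_db
from .calling import (
    RunMetrics,
    assign_and_pileup,
    call_variants,
    calls_to_frame,
    classify_plasmy,
    run_metrics_report,
    write_vcf,
)
from .clonality import (
    build_clonal_tree,
    classify_trunk_branch_private,
    clonal_verdict,
    to_newick,
    venn_summary,
    write_clonality_report,
)
from .filters import apply_filters
from .panel import assign_pools, design_panel, write_panel
from .reference import load_packaged_reference, load_reference, load_regions
from .simulate import SimConfig, make_sample_sheet, simulate_patient, simulate_reads, write_truth

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


class PanelParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_amplicons: int = Field(108, ge=1)
    mean_length: int = Field(160, ge=60, le=200)
    min_overlap: int = Field(6, ge=1)
    primer_length: int = Field(22, ge=10)
    n_pools: int = Field(4, ge=1)


class Thresholds(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_depth: int = Field(30, ge=1)
    min_vaf: float = Field(0.05, ge=0.0, le=1.0)
    min_strand_balance: float = Field(0.2, ge=0.0, le=0.5)
    homoplasmy_vaf: float = Field(0.95, ge=0.0, le=1.0)


class FilterParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    vaf_tolerance: float = Field(0.05, ge=0.0, le=1.0)
    min_patients: int = Field(3, ge=2)
    end_margin: int = Field(5, ge=0)
    noise_quantile: float = Field(0.99, ge=0.0, le=1.0)


class SimulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_patients: int = Field(3, ge=1)
    lesions_min: int = Field(2, ge=1)
    lesions_max: int = Field(4, ge=1)
    n_germline: int = Field(10, ge=0)
    n_trunk: int = Field(3, ge=0)
    n_branch: int = Field(2, ge=0)
    n_private: int = Field(2, ge=0)
    depth_mean: float = Field(2000.0, gt=0)
    depth_dispersion: float = Field(20.0, gt=0)
    deamination_rate: float = Field(0.005, ge=0.0, le=1.0)
    sequencing_error_rate: float = Field(0.001, ge=0.0, le=1.0)
    off_target_fraction: float = Field(0.025, ge=0.0, le=0.99)
    indel_fraction: float = Field(0.1, ge=0.0, le=1.0)
    clonal_drift: float = Field(1.0, gt=0.0)
    read_length: int = Field(300, ge=100)

    def to_sim_config(self, seed: int) -> SimConfig:
        return SimConfig(
            n_patients=self.n_patients,
            lesions_per_patient=(self.lesions_min, self.lesions_max),
            n_germline=self.n_germline, n_trunk=self.n_trunk,
            n_branch=self.n_branch, n_private=self.n_private,
            depth_mean=self.depth_mean, depth_dispersion=self.depth_dispersion,
            deamination_rate=self.deamination_rate,
            sequencing_error_rate=self.sequencing_error_rate,
            off_target_fraction=self.off_target_fraction,
            indel_fraction=self.indel_fraction, clonal_drift=self.clonal_drift,
            read_length=self.read_length, seed=seed,
        )


class ReadsEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")
    patient: str
    lesion: str
    r1: str
    r2: str


class InputBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reads: list[ReadsEntry]


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    reference: Optional[str] = None
    outdir: str
    seed: int = 0
    log_level: str = "INFO"
    panel: PanelParams = PanelParams()
    thresholds: Thresholds = Thresholds()
    filters: FilterParams = FilterParams()
    simulation: Optional[SimulationBlock] = None
    input: Optional[InputBlock] = None

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "PipelineConfig":
        if (self.simulation is None) == (self.input is None):
            raise ValueError("exactly one of 'simulation' and 'input' must be present")
        return self


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config; unknown keys and range violations
    are reported with their key paths."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as e:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in e.errors()
        )
        raise PipelineError(f"invalid config {path}: {details}") from e


def _config_hash(config: PipelineConfig) -> str:
    blob = config.model_dump_json().encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages into ``config.outdir``; returns the output root.

    Layout: ``panel/``, ``reads/``, ``truth/``, ``vcf/``, ``metrics.tsv``,
    ``calls_pass.tsv``, ``calls_review.tsv``, ``clonality/<patient>.tsv``,
    ``trees/<patient>.nwk``, ``verdicts.tsv``, ``run.log``.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("mtlineage")
    root.addHandler(handler)
    root.setLevel(config.log_level)
    try:
        logger.info("mtlineage %s, config hash %s", __version__, _config_hash(config))
        logger.info("config: %s", config.model_dump_json())
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> Path:
    reference = (
        load_reference(config.reference) if config.reference else load_packaged_reference()
    )
    regions = load_regions()
    db = load_polymorphism_db()

    # ---- panel
    panel = design_panel(
        reference,
        n_amplicons=config.panel.n_amplicons,
        mean_length=config.panel.mean_length,
        min_overlap=config.panel.min_overlap,
        primer_length=config.panel.primer_length,
    )
    panel = assign_pools(panel, config.panel.n_pools)
    write_panel(panel, out / "panel")
    logger.info("panel: %d amplicons in %d pools", len(panel.amplicons), config.panel.n_pools)

    # ---- reads (simulated or provided)
    lesion_reads: list[tuple[str, str, Path, Path]] = []
    if config.simulation is not None:
        sim = config.simulation.to_sim_config(config.seed)
        (out / "reads").mkdir(exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        ss = np.random.SeedSequence(config.seed)
        patient_seeds = ss.spawn(sim.n_patients)
        truths = []
        patients: dict[str, list[str]] = {}
        for i in range(sim.n_patients):
            pid = f"P{i + 1:02d}"
            rng = np.random.default_rng(patient_seeds[i])
            tree, truth = simulate_patient(sim, panel, reference, pid, rng)
            truths.append(truth)
            lesions = sorted(truth["lesion"].unique())
            patients[pid] = lesions
            for lesion in lesions:
                r1 = out / "reads" / f"{pid}_{lesion}_R1.fastq"
                r2 = out / "reads" / f"{pid}_{lesion}_R2.fastq"
                simulate_reads(truth, panel, sim, lesion, rng, r1, r2, patient_id=pid)
                lesion_reads.append((pid, lesion, r1, r2))
        truth_all = pd.concat(truths, ignore_index=True)
        write_truth(truth_all, out / "truth" / "truth.tsv")
        sheet_rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(
            sim.n_patients + 1)[-1])
        make_sample_sheet(patients, sheet_rng).to_csv(
            out / "sample_sheet.tsv", sep="\t", index=False)
        logger.info("simulated %d patients, %d lesions", sim.n_patients, len(lesion_reads))
    else:
        for entry in config.input.reads:
            lesion_reads.append((entry.patient, entry.lesion, Path(entry.r1), Path(entry.r2)))

    # ---- calling
    (out / "vcf").mkdir(exist_ok=True)
    th = config.thresholds
    pileups = {}
    metrics: dict[str, RunMetrics] = {}
    frames = []
    for pid, lesion, r1, r2 in lesion_reads:
        pileup, m = assign_and_pileup(r1, r2, panel, reference)
        calls = call_variants(pileup, th.min_depth, th.min_vaf, th.min_strand_balance)
        calls = [classify_plasmy(c, th.homoplasmy_vaf) for c in calls]
        sample = f"{pid}_{lesion}"
        write_vcf(calls, reference, out / "vcf" / f"{sample}.vcf", sample)
        pileups[(pid, lesion)] = pileup
        metrics[sample] = m
        frames.append(calls_to_frame(calls, pid, lesion, reference.length))
        logger.info("called %s: %d raw calls, specificity %.2f%%",
                    sample, len(calls), m.specificity)
    run_metrics_report(metrics, out / "metrics.tsv")
    cohort = pd.concat(frames, ignore_index=True)

    # ---- annotation + filtering
    cohort = annotate_polymorphisms(cohort, db)
    pass_table, review = apply_filters(
        cohort, panel, regions, pileups,
        vaf_tolerance=config.filters.vaf_tolerance,
        min_patients=config.filters.min_patients,
        end_margin=config.filters.end_margin,
        noise_quantile=config.filters.noise_quantile,
    )
    pass_table.to_csv(out / "calls_pass.tsv", sep="\t", index=False)
    review.to_csv(out / "calls_review.tsv", sep="\t", index=False)
    logger.info("filtering: %d pass, %d review", len(pass_table), len(review))

    # ---- clonality
    (out / "clonality").mkdir(exist_ok=True)
    (out / "trees").mkdir(exist_ok=True)
    verdict_rows = []
    for pid in sorted(pass_table["patient"].unique()):
        sub = pass_table[pass_table["patient"] == pid]
        lesions = sorted(sub["lesion"].unique())
        if len(lesions) < 2:
            logger.warning("patient %s has one lesion with calls; skipping clonality", pid)
            continue
        assignment = classify_trunk_branch_private(sub, lesions, th.min_vaf)
        tree, conflicts = build_clonal_tree(assignment)
        verdict = clonal_verdict(assignment, tree, conflicts)
        write_clonality_report(assignment, verdict, out / "clonality" / f"{pid}.tsv")
        venn_summary(assignment).to_csv(out / "clonality" / f"{pid}_venn.tsv",
                                        sep="\t", index=False)
        if tree is not None:
            (out / "trees" / f"{pid}.nwk").write_text(to_newick(tree) + "\n")
        verdict_rows.append(dict(
            patient=pid, verdict=verdict.verdict, trunk=verdict.n_trunk,
            branch=verdict.n_branch, private=verdict.n_private,
            polymorphisms=verdict.n_polymorphisms, conflicts=len(verdict.conflicts),
        ))
        logger.info("patient %s: %s", pid, verdict.verdict)
    pd.DataFrame(verdict_rows, columns=[
        "patient", "verdict", "trunk", "branch", "private", "polymorphisms", "conflicts",
    ]).to_csv(out / "verdicts.tsv", sep="\t", index=False)
    return out
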