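"""Orchestration: reproducible end-to-end runs tying the stages together.

``run_simulated_study`` is the in-memory workhorse (simulate each treatment
library, preprocess, annotate, quantify); ``run_pipeline`` wraps it with
file outputs and a manifest recording seeds, parameters and per-stage read
accounting.  All randomness flows from one base seed; each library draws
from a child generator seeded by (seed, library index), so runs are
byte-identical for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import methyl as methyl_mod
from . import termini as termini_mod
from .annotate import AnnotationHit, CascadeConfig, ReferenceDB, write_references
from .preprocess import PreprocessConfig, PreprocessResult, preprocess_reads
from .quantify import ExpressionTable, build_expression_table
from .simchem import (
    Scenario,
    SimConfig,
    TreatmentPlan,
    default_scenario,
    simulate_library,
    write_fastq,
)


@dataclass
class LibraryRun:
    """Everything produced for one library."""

    label: str
    truth: pd.DataFrame
    pre: PreprocessResult
    hits: list[AnnotationHit]
    unannotated: list[str]

    @property
    def n_reads(self) -> int:
        return self.pre.n_input


@dataclass
class StudyResult:
    scenario: Scenario
    libraries: dict[str, LibraryRun]
    table: ExpressionTable


@dataclass
class RunConfig:
    """Serializable configuration for a full run."""

    seed: int = 1
    out_dir: str = "srnachem_run"
    plans: tuple[str, ...] = ("CPA", "CA", "PA", "CP")
    condition: int = 0
    n_tissues: int = 3
    sim: SimConfig = None  # type: ignore[assignment]
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fc_threshold: float = 30.0
    min_full: float = 10.0
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["plans"] = list(self.plans)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "sim" in d and isinstance(d["sim"], dict):
            d["sim"] = SimConfig(**d["sim"])
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "plans" in d:
            d["plans"] = tuple(d["plans"])
        return cls(**d)


def library_rng(seed: int, index: int) -> np.random.Generator:
    """Child generator for library ``index`` of a run seeded with ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([seed, index]))


def preprocess_config_for(sim: SimConfig, base: Optional[PreprocessConfig] = None) -> PreprocessConfig:
    """Preprocessing parameters consistent with the simulator's adapters/UMIs."""
    base = base or PreprocessConfig()
    return dataclasses.replace(
        base,
        adapter3=sim.adapter3,
        umi5_len=sim.umi5_len,
        umi3_len=sim.umi3_len,
    )


def process_library(
    records: Sequence[tuple[str, str, str]],
    db: ReferenceDB,
    pre_cfg: PreprocessConfig,
) -> tuple[PreprocessResult, list[AnnotationHit], list[str]]:
    """Preprocess raw reads and annotate the collapsed sequences."""
    pre = preprocess_reads(records, pre_cfg)
    hits, unannotated = ann.annotate_cascade(
        [c.sequence for c in pre.collapsed], db
    )
    return pre, hits, unannotated


def run_simulated_study(
    scenario: Scenario,
    plans: Sequence[str],
    sim_cfg: SimConfig,
    condition: int = 0,
    pre_cfg: Optional[PreprocessConfig] = None,
    cascade_cfg: Optional[CascadeConfig] = None,
) -> StudyResult:
    """Simulate and process one library per treatment plan."""
    db = ReferenceDB(scenario.references, cascade_cfg)
    pre_cfg = preprocess_config_for(sim_cfg, pre_cfg)
    libraries: dict[str, LibraryRun] = {}
    per_lib = {}
    for i, label in enumerate(plans):
        plan = TreatmentPlan.from_label(label)
        rng = library_rng(sim_cfg.seed, i)
        records, truth = simulate_library(scenario.species, condition, plan, sim_cfg, rng)
        pre, hits, unannotated = process_library(records, db, pre_cfg)
        libraries[label] = LibraryRun(label, truth, pre, hits, unannotated)
        per_lib[label] = (hits, pre.collapsed)
    table = build_expression_table(per_lib)
    return StudyResult(scenario=scenario, libraries=libraries, table=table)


def run_tissue_atlas(
    scenario: Scenario,
    sim_cfg: SimConfig,
    plan_label: str = "CPA",
    cascade_cfg: Optional[CascadeConfig] = None,
) -> StudyResult:
    """One fully treated library per tissue; table columns are tissues."""
    db = ReferenceDB(scenario.references, cascade_cfg)
    pre_cfg = preprocess_config_for(sim_cfg)
    plan = TreatmentPlan.from_label(plan_label)
    libraries: dict[str, LibraryRun] = {}
    per_lib = {}
    for i, tissue in enumerate(scenario.tissues):
        rng = library_rng(sim_cfg.seed, 1000 + i)
        records, truth = simulate_library(scenario.species, i, plan, sim_cfg, rng)
        pre, hits, unannotated = process_library(records, db, pre_cfg)
        libraries[tissue] = LibraryRun(tissue, truth, pre, hits, unannotated)
        per_lib[tissue] = (hits, pre.collapsed)
    table = build_expression_table(per_lib)
    return StudyResult(scenario=scenario, libraries=libraries, table=table)


def compare_treatments(
    study: StudyResult,
    full_label: str,
    reduced_label: str,
    fc_threshold: float = 30.0,
    min_full: float = 10.0,
    pseudocount: float = 0.5,
) -> tuple[list[termini_mod.ResponsiveCall], Optional[list[methyl_mod.MethylCall]]]:
    """Responsive-species calls between a full and a reduced library; when
    the reduced plan omits the AlkB mix, methylation sites are also called."""
    for label in (full_label, reduced_label):
        if label not in study.libraries:
            raise KeyError(f"library {label!r} not in study")
    omitted = termini_mod.REDUCED_LABEL_TO_OMITTED.get(reduced_label)
    if omitted is None:
        full_flags = TreatmentPlan.from_label(full_label)
        red_flags = TreatmentPlan.from_label(reduced_label)
        omitted_set = [
            name
            for name in ("cap_clip", "pnk", "alkb")
            if getattr(full_flags, name) and not getattr(red_flags, name)
        ]
        if len(omitted_set) != 1:
            raise ValueError(
                f"reduced plan {reduced_label!r} must omit exactly one enzyme of {full_label!r}"
            )
        omitted = omitted_set[0]
    layer = study.table.mirna_norm
    calls = termini_mod.call_responsive(
        layer[full_label],
        layer[reduced_label],
        omitted,
        classes=study.table.meta["class"],
        fc_threshold=fc_threshold,
        min_full=min_full,
        pseudocount=pseudocount,
    )
    m_calls = None
    if omitted == "alkb":
        refs = {r.ref_id: r for r in study.scenario.references}
        weights_no = dict(
            zip(study.table.counts.index, study.table.counts[reduced_label])
        )
        weights_with = dict(
            zip(study.table.counts.index, study.table.counts[full_label])
        )
        pile_no = methyl_mod.build_pileup(study.libraries[reduced_label].hits, weights_no, refs)
        pile_with = methyl_mod.build_pileup(study.libraries[full_label].hits, weights_with, refs)
        m_calls = methyl_mod.call_methylation_sites(pile_no, pile_with)
    return calls, m_calls


def _collapsed_frame(pre: PreprocessResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sequence": c.sequence, "unique_count": c.unique_count, "raw_count": c.raw_count}
            for c in pre.collapsed
        ]
    )


def run_pipeline(config: RunConfig, write_fastqs: bool = False) -> Path:
    """End-to-end run with file artifacts and a manifest.

    Simulates the default scenario at ``config.seed``, processes each
    treatment library, writes per-library tables and treatment-comparison
    reports, and records per-stage read accounting (asserted conserved) in
    ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenario = default_scenario(config.seed, n_tissues=config.n_tissues)
    write_references(scenario.references, out / "references.fasta", out / "references.tsv")
    scenario.species_table().to_csv(out / "species_truth.tsv", sep="\t", index=False)

    db = ReferenceDB(scenario.references)
    pre_cfg = preprocess_config_for(config.sim, config.preprocess)
    libraries: dict[str, LibraryRun] = {}
    per_lib = {}
    accounting = {}
    for i, label in enumerate(config.plans):
        plan = TreatmentPlan.from_label(label)
        rng = library_rng(config.sim.seed, i)
        records, truth = simulate_library(
            scenario.species, config.condition, plan, config.sim, rng
        )
        if write_fastqs:
            write_fastq(records, out / f"{label}.fastq.gz")
        truth.to_csv(out / f"{label}.truth.tsv", sep="\t", index=False)
        pre, hits, unannotated = process_library(records, db, pre_cfg)
        libraries[label] = LibraryRun(label, truth, pre, hits, unannotated)
        per_lib[label] = (hits, pre.collapsed)
        _collapsed_frame(pre).to_csv(out / f"{label}.collapsed.tsv", sep="\t", index=False)
        pd.DataFrame(ann.hits_to_rows(hits)).to_csv(
            out / f"{label}.hits.tsv", sep="\t", index=False
        )
        raw_total = sum(c.raw_count for c in pre.collapsed)
        if raw_total != pre.n_accepted:
            raise AssertionError(f"{label}: read accounting not conserved")
        accounting[label] = {
            "reads_in": pre.n_input,
            "accepted": pre.n_accepted,
            "rejected": pre.rejections,
            "collapsed_raw_total": raw_total,
            "unique_molecules": sum(c.unique_count for c in pre.collapsed),
            "annotated": len(hits),
            "unannotated": len(unannotated),
        }

    table = build_expression_table(per_lib)
    table.counts.to_csv(out / "counts.tsv", sep="\t")
    table.rpm.to_csv(out / "rpm.tsv", sep="\t")
    table.mirna_norm.to_csv(out / "mirna_norm.tsv", sep="\t")
    table.meta.to_csv(out / "annotation.tsv", sep="\t")

    study = StudyResult(scenario=scenario, libraries=libraries, table=table)
    full = config.plans[0]
    for reduced in config.plans[1:]:
        calls, m_calls = compare_treatments(
            study, full, reduced, config.fc_threshold, config.min_full, config.pseudocount
        )
        termini_mod.calls_to_frame(calls).to_csv(
            out / f"responsive_{full}_vs_{reduced}.tsv", sep="\t", index=False
        )
        if m_calls is not None:
            methyl_mod.calls_to_frame(m_calls).to_csv(
                out / f"methyl_sites_{full}_vs_{reduced}.tsv", sep="\t", index=False
            )

    manifest = {
        "seed": config.seed,
        "plans": list(config.plans),
        "condition": config.condition,
        "sim": dataclasses.asdict(config.sim),
        "preprocess": dataclasses.asdict(pre_cfg),
        "accounting": accounting,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
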