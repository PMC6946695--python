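"""End-to-end orchestration: load -> QC -> blocked/gap-fill -> consistency
maximization -> alternatives -> growth -> biomass-precursor analysis ->
pathway tally.

A :class:`PipelineConfig` (YAML or constructed in code) names the inputs and
settings; :func:`run_pipeline` executes the stages in order, writing each
stage's outputs before the next starts, and returns a :class:`RunReport`.
Reports are fully deterministic for a fixed config and seed (wall-clock
timings go to the event log, never into the report), so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .bbb import (
    bbb_fold_changes,
    bbb_production_matrix,
    list_bbbs,
    load_pathway_annotation,
    tally_deregulated_pathways,
)
from .gapfill import apply_gapfill, find_blocked_reactions, gapfill, prioritize_blocked
from .io import load_model, write_model
from .model import check_balance, model_summary
from .omics import load_omics
from .remi import (
    RemiSettings,
    build_remi_problem,
    common_and_variable_constraints,
    select_representative,
)
from .synthetic import SyntheticSpec, generate_condition_omics, generate_toy_model
from .thermo import TFASettings, load_thermo_tsv, solve_tfa, write_thermo_tsv
from .omics import write_omics

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All inputs and knobs for one analysis run.

    Either ``model_path`` (with optional omics/thermo/db paths) or
    ``synthetic`` (a SyntheticSpec mapping) must be given.
    """

    output_dir: str = "remiflux_out"
    model_path: Optional[str] = None
    thermo_path: Optional[str] = None
    genes_path: Optional[str] = None
    metabolites_path: Optional[str] = None
    universal_db_path: Optional[str] = None
    pathway_annotation_path: Optional[str] = None
    synthetic: Optional[dict] = None
    variant: str = "tgexm"
    seed: int = 1
    log_level: str = "INFO"
    run_gapfill: bool = True
    run_bbb: bool = True
    remi: dict = field(default_factory=dict)
    tfa: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.model_path is None and self.synthetic is None:
            raise PipelineConfigError("config needs model_path or synthetic")
        for key in ("model_path", "thermo_path", "genes_path", "metabolites_path",
                    "universal_db_path", "pathway_annotation_path"):
            value = getattr(self, key)
            if value is not None and not Path(value).exists():
                raise PipelineConfigError(f"{key} does not exist: {value}")
        if self.synthetic is None:
            variant = self.remi.get("variant", self.variant)
            if variant in ("tgex", "tgexm") and self.genes_path is None:
                raise PipelineConfigError(f"variant {variant} requires genes_path")
            if variant in ("tm", "tgexm") and self.metabolites_path is None:
                raise PipelineConfigError(f"variant {variant} requires metabolites_path")
        RemiSettings(**{"variant": self.variant, **self.remi})
        TFASettings(**self.tfa)

    def content_hash(self) -> str:
        """Hash of the scientific inputs (where outputs/logs go is excluded)."""
        data = asdict(self)
        data.pop("output_dir", None)
        data.pop("log_level", None)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str
    stages: list[str] = field(default_factory=list)
    numbers: dict = field(default_factory=dict)
    status: str = "ok"
    failed_stage: Optional[str] = None
    error: Optional[str] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True) + "\n"


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; stage outputs land under ``config.output_dir``.

    A stage failure aborts the run with a partial report recording the
    failed stage and cause.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        config_hash=config.content_hash(), seed=config.seed, version=__version__
    )
    event_log = open(outdir / "events.log", "w")

    def log_event(stage: str, message: str) -> None:
        event_log.write(f"{time.time():.3f}\t{stage}\t{message}\n")
        event_log.flush()
        logger.info("[%s] %s", stage, message)

    stage = "load"
    try:
        # ------------------------------------------------------------ load
        if config.synthetic is not None:
            spec = SyntheticSpec(**{"seed": config.seed, **config.synthetic})
            model, thermo, truth = generate_toy_model(spec)
            omics = generate_condition_omics(model, truth, spec)
            universal_db = truth.universal_db
            write_model(model, outdir / "model.json")
            write_thermo_tsv(thermo, outdir / "thermo.tsv")
            write_omics(omics, outdir / "genes.tsv", outdir / "metabolites.tsv")
            report.numbers["ground_truth_mcs"] = truth.expected_mcs
            report.numbers["planted_growth_ratio"] = truth.planted_growth_ratio
        else:
            model = load_model(config.model_path)
            thermo = (
                load_thermo_tsv(config.thermo_path) if config.thermo_path else None
            )
            omics = load_omics(config.genes_path, config.metabolites_path)
            universal_db = (
                load_model(config.universal_db_path)
                if config.universal_db_path
                else None
            )
        report.stages.append(stage)
        log_event(stage, f"model {model.id} loaded")

        # -------------------------------------------------------------- qc
        stage = "qc"
        summary = model_summary(model)
        issues = check_balance(model)
        report.numbers["summary"] = summary
        report.numbers["unbalanced_reactions"] = sorted(
            {i.reaction_id for i in issues if i.kind == "imbalanced"}
        )
        report.numbers["unverifiable_reactions"] = sorted(
            {i.reaction_id for i in issues if i.kind == "unverifiable"}
        )
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
        report.stages.append(stage)
        log_event(stage, f"{len(issues)} balance issues")

        # --------------------------------------------------- blocked + fill
        stage = "blocked"
        blocked = find_blocked_reactions(model)
        report.numbers["blocked_count"] = len(blocked)
        report.numbers["blocked_reactions"] = sorted(blocked)
        report.stages.append(stage)
        log_event(stage, f"{len(blocked)} blocked reactions")

        if config.run_gapfill and blocked and universal_db is not None:
            stage = "gapfill"
            tasks = prioritize_blocked(model, blocked, omics)
            if not tasks:
                # no omics support: still attempt the largest blocked group
                from .gapfill import GapfillTask

                tasks = [
                    GapfillTask(target=sorted(blocked)[0], target_type="reaction")
                ]
            fills = []
            for task in tasks:
                sol = gapfill(model, universal_db, task)
                fills.append(
                    {
                        "target": task.target,
                        "feasible": sol.feasible,
                        "added": sol.added_reaction_ids,
                        "size": sol.size,
                        "alternatives": sol.alternative_sets,
                    }
                )
                if sol.feasible:
                    model = apply_gapfill(model, sol)
            report.numbers["gapfills"] = fills
            report.numbers["blocked_after_gapfill"] = len(
                find_blocked_reactions(model)
            )
            with open(outdir / "gapfill.json", "w") as fh:
                json.dump(fills, fh, indent=1, sort_keys=True)
            report.stages.append(stage)
            log_event(stage, f"{len(fills)} gap-fill tasks")

        # ------------------------------------------------------------- remi
        stage = "remi"
        remi_settings = RemiSettings(**{"variant": config.variant, **config.remi})
        tfa_settings = TFASettings(**config.tfa)
        problem = build_remi_problem(
            model, omics, remi_settings, thermo, tfa_settings
        )
        result = problem.solve_mcs()
        report.numbers["tmcs"] = result.tmcs
        report.numbers["tmcs_gene_level"] = result.tmcs_gene_level
        report.numbers["mcs"] = result.mcs
        report.stages.append(stage)
        log_event(stage, f"TMCS={result.tmcs} MCS={result.mcs}")

        stage = "alternatives"
        alternatives = (
            problem.enumerate_alternatives(result.mcs) if result.mcs > 0 else []
        )
        if not alternatives and result.mcs > 0:
            alternatives = [result.active_set]
        report.numbers["n_alternatives"] = len(alternatives)
        if alternatives:
            common, varying = common_and_variable_constraints(alternatives)
            report.numbers["common_constraints"] = len(common)
            report.numbers["varying_constraints"] = len(varying)
            report.numbers["common_by_source"] = {
                "gene": sum(1 for s in common.values() if s == "gene"),
                "metabolite": sum(1 for s in common.values() if s == "metabolite"),
            }
        else:
            common, varying = {}, {}
        with open(outdir / "consistency.json", "w") as fh:
            json.dump(
                {
                    "tmcs": result.tmcs,
                    "mcs": result.mcs,
                    "alternatives": alternatives,
                    "common": sorted(common),
                    "varying": sorted(varying),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        report.stages.append(stage)
        log_event(stage, f"{len(alternatives)} alternatives")

        stage = "growth"
        active = alternatives[0] if alternatives else []
        g_ref, g_pert = problem.condition_growth(active)
        growths = [problem.condition_growth(a) for a in alternatives] or [
            (g_ref, g_pert)
        ]
        import numpy as np

        report.numbers["growth_reference"] = float(np.mean([g[0] for g in growths]))
        report.numbers["growth_reference_std"] = float(np.std([g[0] for g in growths]))
        report.numbers["growth_perturbed"] = float(np.mean([g[1] for g in growths]))
        report.numbers["growth_perturbed_std"] = float(np.std([g[1] for g in growths]))
        report.stages.append(stage)
        log_event(stage, f"growth ref={g_ref:.4g} pert={g_pert:.4g}")

        # -------------------------------------------------------------- bbb
        if config.run_bbb and model.biomass_reaction_id:
            stage = "bbb"
            precursors = list_bbbs(model)
            if alternatives:
                matrices = bbb_production_matrix(problem, precursors, alternatives)
                rep = select_representative(problem, alternatives)
                bbb = bbb_fold_changes(
                    matrices["reference"], matrices["perturbed"], precursors, rep
                )
                bbb.table.to_csv(outdir / "bbb.tsv", sep="\t", index=False)
                report.numbers["bbb_count"] = len(precursors)
                report.numbers["bbb_higher_in_reference"] = bbb.higher_in_reference
                report.numbers["bbb_higher_in_perturbed"] = bbb.higher_in_perturbed
                report.numbers["bbb_unchanged"] = bbb.unchanged
                report.numbers["representative_alternative"] = rep
            else:
                report.numbers["bbb_count"] = len(precursors)
            report.stages.append(stage)
            log_event(stage, f"{len(precursors)} biomass precursors")

        # ------------------------------------------------------------ tally
        if config.pathway_annotation_path and common:
            stage = "pathways"
            annotation = load_pathway_annotation(config.pathway_annotation_path)
            tally = tally_deregulated_pathways(common, annotation)
            report.numbers["pathway_tally"] = tally[:25]
            report.stages.append(stage)
            log_event(stage, f"{len(tally)} pathways tallied")

    except Exception as exc:  # partial report on stage failure
        report.status = "failed"
        report.failed_stage = stage
        report.error = f"{type(exc).__name__}: {exc}"
        log_event(stage, f"FAILED: {exc}")
        event_log.close()
        (outdir / "report.json").write_text(report.to_json())
        raise
    event_log.close()
    (outdir / "report.json").write_text(report.to_json())
    return report


def compare_environments(report_a: RunReport, report_b: RunReport) -> dict:
    """Side-by-side deltas between two completed context-specific runs."""
    if report_a.status != "ok" or report_b.status != "ok":
        raise ValueError("both runs must have completed")
    keys = (
        "tmcs",
        "mcs",
        "n_alternatives",
        "growth_reference",
        "growth_perturbed",
        "blocked_count",
        "bbb_higher_in_reference",
        "bbb_higher_in_perturbed",
    )
    out: dict = {"a": {}, "b": {}, "delta": {}}
    for key in keys:
        va = report_a.numbers.get(key)
        vb = report_b.numbers.get(key)
        out["a"][key] = va
        out["b"][key] = vb
        if isinstance(va, (int, float)) and isinstance(vb, (int, float)):
            out["delta"][key] = vb - va
    ga, gb = report_a.numbers.get("growth_reference"), report_b.numbers.get(
        "growth_reference"
    )
    if ga and gb:
        out["growth_ratio_b_over_a"] = gb / ga
    return out
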