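"""End-to-end orchestration: summarize -> mine -> calibrate -> filter ->
classify -> validate, with logged stage counts and reproducible outputs.

One master seed (the calibration seed) governs every stochastic stage; all
artifacts are plain CSV/JSON and byte-identical across reruns with the same
inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationConfig,
    calibrate_forms,
    filter_significant_rules,
)
from .classify import classify_rules_frame, group_rules, type_census
from .matrix_io import (
    PresenceAbsenceMatrix,
    cohort_summary,
    read_lineages,
    read_presence_matrix,
    write_rules_table,
)
from .mining import MiningConfig, enumerate_candidate_rules
from .validation import summarize_validation

log = logging.getLogger("virorules")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    matrix_path: str | None = None
    matrix_format: str = "wide"
    lineages_path: str | None = None
    out_dir: str = "results/pipeline"
    mining: MiningConfig = field(default_factory=lambda: MiningConfig(max_lhs_size=2))
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    min_support_floor: float | None = None
    min_lift_floor: float | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        mining = MiningConfig(**raw.pop("mining", {}))
        calib = CalibrationConfig(**raw.pop("calibration", {}))
        return cls(mining=mining, calibration=calib, **raw)

    def validate(self) -> None:
        if self.matrix_path is not None and not Path(self.matrix_path).exists():
            raise PipelineError(f"config: matrix path {self.matrix_path!r} does not exist")
        if self.lineages_path is not None and not Path(self.lineages_path).exists():
            raise PipelineError(f"config: lineages path {self.lineages_path!r} does not exist")


def run_pipeline(
    config: PipelineConfig,
    matrix: PresenceAbsenceMatrix | None = None,
    lineages=None,
) -> dict:
    """Execute every stage and return the report bundle.

    ``matrix`` / ``lineages`` may be passed in memory; otherwise they are read
    from the configured paths.  The bundle holds all stage outputs plus the
    counts logged at each stage.
    """
    config.validate()
    if matrix is None:
        if config.matrix_path is None:
            raise PipelineError("config: no matrix provided")
        matrix = read_presence_matrix(config.matrix_path, config.matrix_format)
    if lineages is None and config.lineages_path is not None:
        lineages = read_lineages(config.lineages_path, vocabulary=matrix.virus_ids)

    mcfg = config.mining.resolved(matrix.n_viruses)
    ccfg = config.calibration
    counts: dict = {"n_strains": matrix.n_strains, "n_viruses": matrix.n_viruses,
                    "n_mined_strains": int(matrix.mined_mask(mcfg.include_virus_free_strains).sum())}

    log.info("stage summarize: %d strains x %d viruses", matrix.n_strains, matrix.n_viruses)
    summary = cohort_summary(matrix)

    log.info("stage mine: max_lhs=%d min_support=%.4g min_confidence=%.4g",
             mcfg.max_lhs_size, mcfg.min_support, mcfg.min_confidence)
    candidates = enumerate_candidate_rules(matrix, mcfg)
    counts["candidates_by_form"] = candidates["rule_form"].value_counts().to_dict()

    log.info("stage calibrate: %d permutations, alpha=%.3g, seed=%d",
             ccfg.n_permutations, ccfg.alpha, ccfg.seed)
    candidates_by_form = {
        form: cand_f for form, cand_f in candidates.groupby("rule_form", sort=False)
        if len(cand_f)
    }
    try:
        tables = calibrate_forms(matrix, mcfg, ccfg, candidates_by_form)
    except ValueError as exc:
        raise PipelineError(f"calibrate: {exc}") from exc

    significant_parts = []
    null_rules_seen = 0
    for form, cand_f in candidates_by_form.items():
        table = tables[form]
        null_rules_seen += int(table.n_null.sum())
        sig = filter_significant_rules(
            cand_f.reset_index(drop=True), table,
            min_support=config.min_support_floor, min_lift=config.min_lift_floor,
        )
        significant_parts.append(sig)
        log.info("stage filter [%s]: %d candidates -> %d significant",
                 form, len(cand_f), len(sig))
    significant = (pd.concat(significant_parts, ignore_index=True)
                   if significant_parts else candidates.iloc[0:0].copy())
    counts["significant_by_form"] = (
        significant["rule_form"].value_counts().to_dict() if len(significant) else {}
    )

    log.info("stage classify: %d significant rules", len(significant))
    significant = classify_rules_frame(significant)
    census = type_census(significant)
    grouped = group_rules(significant)
    counts["type_census"] = census

    validation = None
    if lineages is not None:
        log.info("stage validate: %d lineages", len(lineages))
        per_lineage, overall = summarize_validation(significant, lineages)
        validation = {"per_lineage": per_lineage, "overall": overall}
        counts["validation_overall"] = {
            row["rule_form"]: {"predicted": int(row["predicted"]),
                               "confirmed": int(row["confirmed"]),
                               "accuracy": (None if pd.isna(row["accuracy"])
                                            else round(float(row["accuracy"]), 4))}
            for _, row in overall.iterrows()
        }

    return {
        "config": config,
        "matrix": matrix,
        "summary": summary,
        "candidates": candidates,
        "null_pool_size": null_rules_seen,
        "calibration_tables": tables,
        "significant": significant,
        "grouped": grouped,
        "census": census,
        "validation": validation,
        "counts": counts,
        "seed": ccfg.seed,
    }


def export_report(bundle: dict, out_dir) -> dict:
    """Write all tabular artifacts plus machine- and human-readable summaries.

    Returns the paths written.  The JSON summary is deterministic (sorted
    keys, no timestamps) so reruns with the same seed are byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    viruses, strains, hist = bundle["summary"].to_frames()
    for name, df in [("summary_viruses", viruses), ("summary_strains", strains),
                     ("summary_histogram", hist)]:
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)

    for name in ("candidates", "significant"):
        p = out / f"{name}.csv"
        write_rules_table(bundle[name], p)
        paths[name] = str(p)
    p = out / "grouped_rules.csv"
    bundle["grouped"].to_csv(p, index=False)
    paths["grouped_rules"] = str(p)

    for form, table in bundle["calibration_tables"].items():
        p = out / f"calibration_{form}.json"
        table.to_json(p)
        paths[f"calibration_{form}"] = str(p)

    if bundle["validation"] is not None:
        p = out / "validation_per_lineage.csv"
        bundle["validation"]["per_lineage"].to_csv(p, index=False)
        paths["validation_per_lineage"] = str(p)
        p = out / "validation_overall.csv"
        bundle["validation"]["overall"].to_csv(p, index=False)
        paths["validation_overall"] = str(p)

    report = {
        "seed": bundle["seed"],
        "mining": dataclasses.asdict(bundle["config"].mining),
        "alpha": bundle["config"].calibration.alpha,
        "n_permutations": bundle["config"].calibration.n_permutations,
        "null_pool_size": bundle["null_pool_size"],
        "counts": bundle["counts"],
        "global_lift_thresholds": {
            form: t.global_threshold for form, t in bundle["calibration_tables"].items()
        },
    }
    p = out / "report.json"
    p.write_text(json.dumps(report, sort_keys=True, indent=1, default=float))
    paths["report"] = str(p)

    lines = [
        f"strains={bundle['counts']['n_strains']} viruses={bundle['counts']['n_viruses']} "
        f"mined={bundle['counts']['n_mined_strains']}",
        f"candidates: {bundle['counts']['candidates_by_form']}",
        f"significant: {bundle['counts']['significant_by_form']}",
        f"type census: {bundle['census']}",
    ]
    if "validation_overall" in bundle["counts"]:
        lines.append(f"validation: {bundle['counts']['validation_overall']}")
    p = out / "report.txt"
    p.write_text("\n".join(lines) + "\n")
    paths["report_txt"] = str(p)
    return paths
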