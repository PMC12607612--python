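"""End-to-end pipeline: synthetic generation → validation → summaries → risk.

``run_pipeline`` is a pure function of its configuration (including the
seed): rerunning with the same configuration writes bit-identical files.
Stage seeds are derived from the configured seed through a
``numpy.random.SeedSequence`` so the stages are independently reproducible.

Outputs under the configured directory:

* inputs/   — calibration.csv, recovery.csv, survey.csv, intake.csv
* validation_report.csv — per matrix × compound fit, LOD/LOQ, recovery, precision
* summary_table4.csv    — mean ± SD per commodity × compound + PAH4 aggregates
* summary_table5.csv    — detection rates and median (Q1–Q3)
* compliance.csv        — EU maximum-level flags per commodity
* risk_table6.csv       — TEQ, EDI, MOE, concern, critical intakes
* run.log               — one structured line per stage (rows in/out), config
  hash and seed
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, reference
from .compounds import COMPOUNDS
from .config import PipelineConfig
from .quantification import validation_report
from .risk import RiskParams, TEFTable, risk_table_frame, run_risk_table
from .survey import (
    RegulatoryLimits,
    commodity_aggregates,
    compliance_table,
    summarize,
)
from .synthetic_data import (
    CalibrationDesign,
    generate_calibration_set,
    generate_intake,
    generate_spike_recovery,
    generate_survey,
)

REPORT_FILES = (
    "validation_report.csv",
    "summary_table4.csv",
    "summary_table5.csv",
    "compliance.csv",
    "risk_table6.csv",
)


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Derive n reproducible 31-bit stage seeds from the run seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def generate_inputs(config: PipelineConfig, outdir: Path) -> dict[str, pd.DataFrame]:
    """Write the synthetic input tables and return them keyed by name."""
    inputs_dir = outdir / "inputs"
    inputs_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, 4)

    cal_frames = []
    for i, ((matrix, compound), coef) in enumerate(sorted(reference.CALIBRATION.items())):
        design = CalibrationDesign(
            levels=tuple(config.calibration.levels),
            true_slope=coef["slope"],
            true_intercept=coef["intercept"],
            noise_sd=config.calibration.noise_sd,
            is_nominal=config.calibration.is_nominal,
            replicates_per_level=config.calibration.replicates_per_level,
        )
        tbl = generate_calibration_set(design, seeds[0] + i)
        tbl.insert(0, "matrix", matrix)
        tbl.insert(1, "compound", compound)
        cal_frames.append(tbl)
    calibration = pd.concat(cal_frames, ignore_index=True)

    rec_frames = []
    for i, ((matrix, compound), by_level) in enumerate(sorted(reference.RECOVERY_PCT.items())):
        design = CalibrationDesign(
            levels=tuple(config.calibration.levels),
            true_slope=reference.CALIBRATION[(matrix, compound)]["slope"],
            true_intercept=reference.CALIBRATION[(matrix, compound)]["intercept"],
        )
        tbl = generate_spike_recovery(
            design,
            {lvl: pct / 100.0 for lvl, pct in by_level.items()},
            days=config.recovery.days,
            reps_per_day=config.recovery.reps_per_day,
            seed=seeds[1] + i,
            rel_noise_sd=config.recovery.rel_noise_sd,
        )
        tbl.insert(0, "matrix", matrix)
        tbl.insert(1, "compound", compound)
        rec_frames.append(tbl)
    recovery = pd.concat(rec_frames, ignore_index=True)

    survey = generate_survey(
        [s.spec() for s in config.survey_specs], config.n_per_commodity, seeds[2]
    )

    intake_frames = []
    for i, icfg in enumerate(config.intakes):
        draws = generate_intake(icfg.spec(), n=1000, seed=seeds[3] + i)
        intake_frames.append(
            pd.DataFrame({"commodity": icfg.commodity, "intake_g_day": draws})
        )
    intake = pd.concat(intake_frames, ignore_index=True)

    calibration.to_csv(inputs_dir / "calibration.csv", index=False)
    recovery.to_csv(inputs_dir / "recovery.csv", index=False)
    io.write_survey_csv(survey, inputs_dir / "survey.csv")
    intake.to_csv(inputs_dir / "intake.csv", index=False)
    return {
        "calibration": calibration,
        "recovery": recovery,
        "survey": survey,
        "intake": intake,
    }


def validate_stage(
    calibration: pd.DataFrame, recovery: pd.DataFrame, noise_sd: float
) -> pd.DataFrame:
    """Method-validation report per matrix × compound."""
    frames = []
    for (matrix, compound), cal in calibration.groupby(["matrix", "compound"]):
        rec = recovery[
            (recovery["matrix"] == matrix) & (recovery["compound"] == compound)
        ]
        rep = validation_report(cal, rec, noise_sd)
        rep.insert(0, "matrix", matrix)
        rep.insert(1, "compound", compound)
        frames.append(rep)
    return pd.concat(frames, ignore_index=True)


def summarize_stage(
    survey: pd.DataFrame, limits: RegulatoryLimits
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Survey summaries: the mean table, the median/detection table, compliance."""
    summary = summarize(survey)
    aggregates = commodity_aggregates(summary)
    table4 = summary.pivot(index="commodity", columns="compound", values="mean_ug_kg")
    sds = summary.pivot(index="commodity", columns="compound", values="sd_ug_kg")
    table4 = table4[list(COMPOUNDS)].add_suffix("_mean_ug_kg").join(
        sds[list(COMPOUNDS)].add_suffix("_sd_ug_kg")
    )
    table4 = table4.join(aggregates.set_index("commodity")).reset_index()
    table5 = summary[
        [
            "commodity",
            "compound",
            "detection_rate_pct",
            "median_ug_kg",
            "q1_ug_kg",
            "q3_ug_kg",
        ]
    ].copy()
    compliance = compliance_table(aggregates, limits)
    return table4, table5, compliance


def risk_stage(table4: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """TEQ/EDI/MOE risk table from the per-commodity mean concentrations."""
    tefs = TEFTable(config.tefs)
    intakes = {i.commodity: i for i in config.intakes}
    means = {}
    params = {}
    for _, row in table4.iterrows():
        commodity = row["commodity"]
        if commodity not in intakes:
            raise KeyError(f"no intake scenario for commodity {commodity!r}")
        means[commodity] = {c: float(row[f"{c}_mean_ug_kg"]) for c in COMPOUNDS}
        icfg = intakes[commodity]
        params[commodity] = RiskParams(
            bmdl10_bap=config.risk.bmdl10_bap,
            bmdl10_sum4=config.risk.bmdl10_sum4,
            body_weight=config.risk.body_weight,
            moe_threshold=config.risk.moe_threshold,
            intake_mean=icfg.mean_intake,
            intake_p95=icfg.p95_intake,
        )
    return risk_table_frame(run_risk_table(means, params, tefs))


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage and write all report files plus the run log."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[dict] = []

    def log(stage: str, **counts: object) -> None:
        log_lines.append({"stage": stage, **counts})

    inputs = generate_inputs(config, outdir)
    log(
        "generate",
        calibration_rows=len(inputs["calibration"]),
        recovery_rows=len(inputs["recovery"]),
        survey_rows=len(inputs["survey"]),
        intake_rows=len(inputs["intake"]),
    )

    validation = validate_stage(
        inputs["calibration"], inputs["recovery"], config.calibration.noise_sd
    )
    io.write_table(validation, outdir / "validation_report.csv")
    log("validate", rows=len(validation))

    limits = RegulatoryLimits(config.limits.bap_limit, config.limits.sum4_limit)
    table4, table5, compliance = summarize_stage(inputs["survey"], limits)
    io.write_table(table4, outdir / "summary_table4.csv")
    io.write_table(table5, outdir / "summary_table5.csv")
    io.write_table(compliance, outdir / "compliance.csv")
    log("summarize", table4_rows=len(table4), table5_rows=len(table5))

    risk = risk_stage(table4, config)
    io.write_table(risk, outdir / "risk_table6.csv")
    log("risk", rows=len(risk))

    header = {"config_hash": config.config_hash(), "seed": config.seed}
    with open(outdir / "run.log", "w", encoding="utf-8") as fh:
        fh.write(json.dumps(header) + "\n")
        for line in log_lines:
            fh.write(json.dumps(line) + "\n")

    return {name: outdir / name for name in REPORT_FILES} | {
        "run.log": outdir / "run.log"
    }
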