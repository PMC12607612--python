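"""Pipeline configuration: validated settings and the shipped demo scenario.

The configuration is a single pydantic model serialisable to/from YAML.  The
demo configuration reproduces the study conditions of the reference survey:
5-level calibration with the published response lines, per-commodity ×
compound censored-lognormal concentration models whose detection
probabilities and means match the published summaries, spike-recovery
replicate sets at the published mean recoveries, and illustrative
mean/95th-percentile intake scenarios (national intake records are not
published, so the shipped values are synthetic stand-ins).
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from . import reference
from .compounds import COMPOUNDS, DEFAULT_TEFS
from .synthetic_data import (
    CalibrationDesign,
    CensoredLognormalSpec,
    IntakeSpec,
)

#: Default lognormal shape for detected concentrations (dimensionless).
DEFAULT_LOG_SD = 0.8

#: Illustrative daily-intake scenarios, g/day (synthetic stand-ins).
DEMO_INTAKE: dict[str, tuple[float, float]] = {
    "Mustard": (0.6, 2.0),
    "Nutmeg": (0.05, 0.15),
    "Black pepper": (1.0, 3.0),
    "Sichuan pepper": (0.2, 0.7),
    "Cinnamon": (0.6, 2.0),
    "Turmeric": (0.3, 1.0),
    "Basil": (0.12, 0.4),
    "Oregano": (0.12, 0.4),
    "Parsley": (0.12, 0.4),
    "Rosemary": (0.06, 0.2),
    "Bay leaves": (0.1, 0.3),
}

#: Demo blank-baseline noise of the area ratio (area-ratio units), at the
#: scale implied by the published detection limits.
DEMO_NOISE_SD = 2.0e-4


class CalibrationCfg(BaseModel):
    levels: list[float] = list(reference.CALIBRATION_LEVELS)
    true_slope: float = 0.0085
    true_intercept: float = -0.0013
    noise_sd: float = Field(default=DEMO_NOISE_SD, ge=0)
    is_nominal: float = Field(default=100.0, gt=0)
    replicates_per_level: int = Field(default=1, ge=1)

    def design(self) -> CalibrationDesign:
        return CalibrationDesign(
            levels=tuple(self.levels),
            true_slope=self.true_slope,
            true_intercept=self.true_intercept,
            noise_sd=self.noise_sd,
            is_nominal=self.is_nominal,
            replicates_per_level=self.replicates_per_level,
        )


class SurveySpecCfg(BaseModel):
    commodity: str
    compound: str
    detect_prob: float = Field(ge=0, le=1)
    log_mean: float
    log_sd: float = Field(ge=0)
    loq: float = Field(gt=0)

    def spec(self) -> CensoredLognormalSpec:
        return CensoredLognormalSpec(
            commodity=self.commodity,
            compound=self.compound,
            detect_prob=self.detect_prob,
            log_mean=self.log_mean,
            log_sd=self.log_sd,
            loq=self.loq,
        )


class IntakeCfg(BaseModel):
    commodity: str
    mean_intake: float = Field(gt=0)
    p95_intake: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "IntakeCfg":
        if self.p95_intake < self.mean_intake:
            raise ValueError("p95_intake must be at least mean_intake")
        return self

    def spec(self) -> IntakeSpec:
        return IntakeSpec(self.commodity, self.mean_intake, self.p95_intake)


class RecoveryCfg(BaseModel):
    days: int = Field(default=3, ge=1)
    reps_per_day: int = Field(default=3, ge=1)
    rel_noise_sd: float = Field(default=0.01, ge=0)


class RiskCfg(BaseModel):
    bmdl10_bap: float = Field(default=reference.BMDL10_BAP, gt=0)
    bmdl10_sum4: float = Field(default=reference.BMDL10_SUM4, gt=0)
    body_weight: float = Field(default=reference.BODY_WEIGHT_KG, gt=0)
    moe_threshold: float = Field(default=reference.MOE_THRESHOLD, gt=0)


class LimitsCfg(BaseModel):
    bap_limit: float = Field(default=reference.EU_BAP_LIMIT, gt=0)
    sum4_limit: float = Field(default=reference.EU_SUM4_LIMIT, gt=0)


class PipelineConfig(BaseModel):
    seed: int = 0
    outdir: str = "results"
    n_per_commodity: int = Field(default=reference.N_PER_COMMODITY, ge=1)
    tefs: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_TEFS))
    calibration: CalibrationCfg = Field(default_factory=CalibrationCfg)
    recovery: RecoveryCfg = Field(default_factory=RecoveryCfg)
    survey_specs: list[SurveySpecCfg] = Field(default_factory=list)
    intakes: list[IntakeCfg] = Field(default_factory=list)
    risk: RiskCfg = Field(default_factory=RiskCfg)
    limits: LimitsCfg = Field(default_factory=LimitsCfg)

    @model_validator(mode="after")
    def _commodities_consistent(self) -> "PipelineConfig":
        surveyed = {s.commodity for s in self.survey_specs}
        for i in self.intakes:
            if surveyed and i.commodity not in surveyed:
                raise ValueError(
                    f"intake scenario for {i.commodity!r} has no survey spec"
                )
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def _log_mean_for(mean: float, detect_prob: float, loq: float, log_sd: float) -> float:
    """Location solved so detect_prob × E[detected] matches the target mean.

    Censored samples contribute 0 to the mean, so the detected-part mean is
    mean/detect_prob; truncation of the lognormal at the LOQ is ignored when
    inverting (adequate when the LOQ sits in the lower tail).
    """
    if detect_prob <= 0 or mean <= 0:
        return math.log(loq)
    return math.log(mean / detect_prob) - log_sd**2 / 2.0


def demo_survey_specs(log_sd: float = DEFAULT_LOG_SD) -> list[SurveySpecCfg]:
    """Censored-lognormal specs matching the reference survey's summaries."""
    means = reference.survey_means()
    rates = reference.detection_rates()
    specs = []
    for commodity in reference.COMMODITIES:
        for compound in COMPOUNDS:
            p = rates.loc[commodity, compound] / 100.0
            loq = reference.loq_of(commodity, compound)
            specs.append(
                SurveySpecCfg(
                    commodity=commodity,
                    compound=compound,
                    detect_prob=p,
                    log_mean=_log_mean_for(
                        float(means.loc[commodity, compound]), p, loq, log_sd
                    ),
                    log_sd=log_sd,
                    loq=loq,
                )
            )
    return specs


def default_config(seed: int = 0, outdir: str = "results") -> PipelineConfig:
    """The shipped demo configuration emulating the reference survey."""
    return PipelineConfig(
        seed=seed,
        outdir=outdir,
        survey_specs=demo_survey_specs(),
        intakes=[
            IntakeCfg(commodity=c, mean_intake=m, p95_intake=p)
            for c, (m, p) in DEMO_INTAKE.items()
        ],
    )
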