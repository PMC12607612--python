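"""Synthetic generators for every input the pipeline consumes.

The raw survey data (GC-MS peak areas, per-sample concentrations, national
intake records) are not publicly deposited, so the pipeline is exercised on
synthetic inputs whose statistical structure matches the study conditions:

* 5-level linear internal-standard calibration with additive Gaussian noise
  on the analyte/IS area ratio;
* spike-recovery replicate sets grouped by day, for intra/inter-day
  accuracy and precision;
* left-censored per-sample concentrations — each compound is below the LOQ
  with probability ``1 − detect_prob`` (stored as 0 with a censored flag),
  otherwise drawn from a lognormal truncated below at the LOQ;
* right-skewed daily-intake draws from a two-parameter lognormal solved from
  a (mean, 95th percentile) scenario pair.

Every generator is a pure function of its specification and an explicit
integer seed: identical inputs give bit-identical outputs, and no global
random state is touched.  Compounds within a sample are generated
independently; within-sample correlation is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compounds import validate_compound

#: Nominal internal-standard peak area (arbitrary area units). Only the
#: analyte/IS ratio is statistically meaningful; the absolute scale is fixed
#: so generated tables carry realistic-looking raw areas.
IS_NOMINAL_AREA: float = 1.0e6

_Z95 = float(stats.norm.ppf(0.95))  # 1.6448536...


@dataclass(frozen=True)
class CalibrationDesign:
    """Design of a 5-level internal-standard calibration experiment.

    Parameters
    ----------
    levels
        Standard concentrations in µg/kg; strictly positive and increasing.
    true_slope, true_intercept
        Linear response of the analyte/IS area ratio to concentration.
    noise_sd
        SD of additive Gaussian noise on the area ratio (area-ratio units).
    is_nominal
        Internal-standard spike level in µg/kg (metadata; the IS peak area
        itself is held at :data:`IS_NOMINAL_AREA`).
    replicates_per_level
        Independent injections per standard level.
    """

    levels: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0)
    true_slope: float = 0.0085
    true_intercept: float = -0.0013
    noise_sd: float = 0.0
    is_nominal: float = 100.0
    replicates_per_level: int = 1

    def __post_init__(self) -> None:
        levels = tuple(float(x) for x in self.levels)
        object.__setattr__(self, "levels", levels)
        if not levels:
            raise ValueError("levels must be non-empty")
        if any(x <= 0 for x in levels):
            raise ValueError("calibration levels must be strictly positive")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("calibration levels must be strictly increasing")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be at least 1")


@dataclass(frozen=True)
class CensoredLognormalSpec:
    """Left-censored lognormal model for one commodity × compound cell.

    A sample is detected (≥ LOQ) with probability ``detect_prob``; detected
    concentrations follow ``Lognormal(log_mean, log_sd)`` truncated below at
    ``loq``.  Censored samples are recorded as 0 with a censored flag.
    """

    commodity: str
    compound: str
    detect_prob: float
    log_mean: float
    log_sd: float
    loq: float

    def __post_init__(self) -> None:
        validate_compound(self.compound)
        if not 0.0 <= self.detect_prob <= 1.0:
            raise ValueError("detect_prob must lie in [0, 1]")
        if self.log_sd < 0:
            raise ValueError("log_sd must be non-negative")
        if self.loq <= 0:
            raise ValueError("loq must be positive")


@dataclass(frozen=True)
class IntakeSpec:
    """Daily-intake scenario for one commodity: mean and 95th percentile (g/day)."""

    commodity: str
    mean_intake: float
    p95_intake: float

    def __post_init__(self) -> None:
        if self.mean_intake < 0:
            raise ValueError("mean_intake must be non-negative")
        if self.p95_intake < self.mean_intake:
            raise ValueError("p95_intake must be at least mean_intake")


def generate_calibration_set(design: CalibrationDesign, seed: int) -> pd.DataFrame:
    """Simulate analyte and internal-standard peak areas for a calibration run.

    Returns a table with one row per level × replicate and columns
    ``level`` (µg/kg), ``replicate``, ``analyte_area`` and ``is_area``; the
    area ratio follows the design's line plus Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    levels = np.repeat(design.levels, design.replicates_per_level)
    ratio = design.true_slope * levels + design.true_intercept
    if design.noise_sd > 0:
        ratio = ratio + rng.normal(0.0, design.noise_sd, size=levels.size)
    is_area = np.full(levels.size, IS_NOMINAL_AREA)
    return pd.DataFrame(
        {
            "level": levels,
            "replicate": np.tile(
                np.arange(1, design.replicates_per_level + 1), len(design.levels)
            ),
            "analyte_area": ratio * is_area,
            "is_area": is_area,
        }
    )


def _draw_detected(
    rng: np.random.Generator, spec: CensoredLognormalSpec, n: int
) -> np.ndarray:
    """Lognormal draws conditioned ≥ loq, via inverse-CDF of the truncated law."""
    if spec.log_sd == 0.0:
        point = float(np.exp(spec.log_mean))
        if point < spec.loq:
            # Degenerate law sits wholly below the LOQ: nothing is detectable.
            raise ValueError(
                "log_sd=0 with exp(log_mean) below loq leaves no detectable mass"
            )
        return np.full(n, point)
    dist = stats.lognorm(s=spec.log_sd, scale=np.exp(spec.log_mean))
    f_loq = dist.cdf(spec.loq)
    u = rng.uniform(size=n)
    return dist.ppf(f_loq + u * (1.0 - f_loq))


def generate_survey(
    specs: Sequence[CensoredLognormalSpec], n_per_commodity: int, seed: int
) -> pd.DataFrame:
    """Simulate a left-censored market survey.

    Returns a long table with columns ``commodity``, ``sample_id``,
    ``compound``, ``concentration`` (µg/kg, 0 when censored), ``censored``
    and ``loq``.  Compounds are drawn independently per sample.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if n_per_commodity < 1:
        raise ValueError("n_per_commodity must be at least 1")
    rng = np.random.default_rng(seed)
    frames = []
    for spec in specs:
        detected = rng.uniform(size=n_per_commodity) < spec.detect_prob
        conc = np.zeros(n_per_commodity)
        n_det = int(detected.sum())
        if n_det:
            conc[detected] = _draw_detected(rng, spec, n_det)
        frames.append(
            pd.DataFrame(
                {
                    "commodity": spec.commodity,
                    "sample_id": [
                        f"{spec.commodity}-{i:05d}" for i in range(1, n_per_commodity + 1)
                    ],
                    "compound": spec.compound,
                    "concentration": conc,
                    "censored": ~detected,
                    "loq": spec.loq,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_spike_recovery(
    design: CalibrationDesign,
    true_recovery: float | Mapping[float, float],
    days: int,
    reps_per_day: int,
    seed: int,
    rel_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate spike-recovery replicates grouped by day.

    ``true_recovery`` is either one fraction for all spike levels or a
    mapping level → fraction; measured concentrations are
    ``level × recovery × (1 + N(0, rel_noise_sd))``.  Returns columns
    ``day``, ``level``, ``replicate``, ``measured`` (µg/kg).
    """
    if days < 1 or reps_per_day < 1:
        raise ValueError("days and reps_per_day must be at least 1")
    if rel_noise_sd < 0:
        raise ValueError("rel_noise_sd must be non-negative")

    def recovery_at(level: float) -> float:
        r = true_recovery[level] if isinstance(true_recovery, Mapping) else true_recovery
        if not 0.0 < r <= 1.5:
            raise ValueError("true_recovery must lie in (0, 1.5]")
        return float(r)

    rng = np.random.default_rng(seed)
    rows = []
    for day in range(1, days + 1):
        for level in design.levels:
            base = level * recovery_at(level)
            noise = rng.normal(0.0, rel_noise_sd, size=reps_per_day)
            for rep, eps in enumerate(noise, start=1):
                rows.append((day, level, rep, base * (1.0 + eps)))
    return pd.DataFrame(rows, columns=["day", "level", "replicate", "measured"])


def solve_lognormal_from_mean_p95(mean: float, p95: float) -> tuple[float, float]:
    """Solve lognormal (µ, σ) from its mean and 95th percentile.

    Uses E[X] = exp(µ + σ²/2) and P95 = exp(µ + z₀.₉₅ σ); the smaller root in
    σ is taken so the quantile constraint sits on the upper tail.  Requires
    ``mean ≤ p95 ≤ mean × exp(z²/2)`` (≈ 3.87 × mean); outside that range no
    two-parameter lognormal matches both moments.
    """
    if mean <= 0:
        raise ValueError("mean intake must be positive")
    if p95 < mean:
        raise ValueError("p95 below mean: no lognormal solution")
    gap = np.log(p95) - np.log(mean)  # = z σ − σ²/2 ≥ 0
    disc = _Z95**2 - 2.0 * gap
    if disc < 0:
        raise ValueError(
            "p95/mean ratio too large for a two-parameter lognormal "
            f"(max ≈ {np.exp(_Z95 ** 2 / 2):.3f})"
        )
    sigma = _Z95 - float(np.sqrt(disc))
    mu = float(np.log(mean)) - sigma**2 / 2.0
    return mu, sigma


def generate_intake(spec: IntakeSpec, n: int, seed: int) -> np.ndarray:
    """Draw n daily-intake values (g/day) from the scenario's lognormal fit."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed)
    if spec.p95_intake == spec.mean_intake:
        return np.full(n, float(spec.mean_intake))
    mu, sigma = solve_lognormal_from_mean_p95(spec.mean_intake, spec.p95_intake)
    return rng.lognormal(mu, sigma, size=n)
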