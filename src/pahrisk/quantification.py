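"""Method-validation computations for internal-standard GC-MS quantification.

Calibration is ordinary least squares of the analyte/IS peak-area ratio on
standard concentration.  Detection limits follow the signal-to-noise
convention: LOD = 3.3 σ/slope and LOQ = 10 σ/slope, with σ the baseline
noise of the area ratio estimated from blank replicates.  Recovery is the
spiked-minus-unspiked difference over the spike level; accuracy is the mean
measured concentration over the spike level; precision is the relative
standard deviation (RSD), within a day (intra) or across day means (inter).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

SN_LOD = 3.3
SN_LOQ = 10.0


class DegenerateDesignError(ValueError):
    """Calibration points carry no concentration spread."""


class InsufficientDataError(ValueError):
    """Too few points or replicates for the requested statistic."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted line mapping concentration (µg/kg) to analyte/IS area ratio."""

    slope: float
    intercept: float
    r_squared: float
    lod: float | None = None  # µg/kg
    loq: float | None = None  # µg/kg

    def predict(self, concentration: float) -> float:
        """Area ratio expected at a concentration (forward direction)."""
        return self.slope * concentration + self.intercept

    def with_limits(self, noise_sd: float) -> "CalibrationCurve":
        """Attach LOD/LOQ derived from a blank-baseline noise SD."""
        lod, loq = estimate_lod_loq(noise_sd, self.slope)
        return replace(self, lod=lod, loq=loq)


@dataclass(frozen=True)
class ValidationStats:
    """Accuracy and precision at one spike level."""

    level: float  # µg/kg
    n: int
    accuracy_pct: float
    rsd_pct: float
    scope: Literal["intra", "inter"]


def fit_calibration(points: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary least squares of area ratio on concentration.

    Requires at least 3 points over at least 2 distinct concentrations.
    R² is the coefficient of determination of the fit; with zero residuals
    (including an exactly constant response) it equals 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InsufficientDataError("need at least 3 (concentration, ratio) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise DegenerateDesignError("all calibration concentrations are identical")
    res = stats.linregress(x, y)
    fitted = res.slope * x + res.intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(slope=float(res.slope), intercept=float(res.intercept), r_squared=r2)


def estimate_lod_loq(noise_sd: float, slope: float) -> tuple[float, float]:
    """LOD and LOQ (µg/kg) from baseline noise via S/N = 3.3 and S/N = 10."""
    if slope <= 0:
        raise ValueError("slope must be positive to convert noise to concentration")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    return SN_LOD * noise_sd / slope, SN_LOQ * noise_sd / slope


def quantify(area_ratio: float, curve: CalibrationCurve) -> float:
    """Back-calculate concentration (µg/kg) from an area ratio.

    Negative results are returned as-is; censoring to zero is a survey-level
    decision, not a calibration one.
    """
    if curve.slope == 0:
        raise ValueError("cannot invert a calibration curve with zero slope")
    return (area_ratio - curve.intercept) / curve.slope


def recovery_pct(
    spiked_measured: float, unspiked_measured: float, spike_level: float
) -> float:
    """Spike recovery in percent: 100 × (spiked − unspiked) / spike level."""
    if spike_level <= 0:
        raise ValueError("spike_level must be positive")
    return 100.0 * (spiked_measured - unspiked_measured) / spike_level


def precision_stats(
    measurements_by_day: Mapping[object, Iterable[float]] | Sequence[float],
    spike_level: float,
    scope: Literal["intra", "inter"],
) -> ValidationStats:
    """Accuracy (%) and RSD (%) at one spike level.

    ``intra`` pools replicates within a single day (exactly one day must be
    supplied; a bare sequence is treated as one day's replicates); ``inter``
    computes the statistics over per-day means.  Accuracy is
    100 × mean/spike level; RSD is 100 × SD/mean with the n−1 denominator.
    """
    if spike_level <= 0:
        raise ValueError("spike_level must be positive")
    if not isinstance(measurements_by_day, Mapping):
        measurements_by_day = {1: list(measurements_by_day)}
    groups = {day: np.asarray(list(v), dtype=float) for day, v in measurements_by_day.items()}
    if not groups:
        raise InsufficientDataError("no measurements supplied")
    if scope == "intra":
        if len(groups) != 1:
            raise ValueError("intra-day scope expects measurements from one day")
        values = next(iter(groups.values()))
    elif scope == "inter":
        if any(v.size == 0 for v in groups.values()):
            raise InsufficientDataError("empty day group")
        values = np.array([v.mean() for v in groups.values()])
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if values.size < 2:
        raise InsufficientDataError("need at least 2 replicates for RSD")
    mean = float(values.mean())
    if mean == 0:
        raise ZeroDivisionError("RSD undefined: mean measurement is zero")
    sd = float(values.std(ddof=1))
    return ValidationStats(
        level=spike_level,
        n=int(values.size),
        accuracy_pct=100.0 * mean / spike_level,
        rsd_pct=100.0 * sd / mean,
        scope=scope,
    )


def fit_calibration_table(table: pd.DataFrame) -> CalibrationCurve:
    """Fit a curve from a generated calibration table (level, analyte/IS areas)."""
    ratio = table["analyte_area"] / table["is_area"]
    return fit_calibration(list(zip(table["level"], ratio)))


def validation_report(
    calibration: pd.DataFrame,
    recovery: pd.DataFrame,
    noise_sd: float,
) -> pd.DataFrame:
    """One-row validation summary: fit, limits, per-level recovery and precision.

    ``calibration`` follows the generated calibration schema; ``recovery``
    has columns day, level, replicate, measured.  Intra-day statistics use
    the first day; inter-day statistics use day means.
    """
    curve = fit_calibration_table(calibration).with_limits(noise_sd)
    rows = []
    first_day = recovery["day"].min()
    for level, grp in recovery.groupby("level"):
        by_day = {d: g["measured"].tolist() for d, g in grp.groupby("day")}
        intra = precision_stats({first_day: by_day[first_day]}, level, "intra")
        inter = precision_stats(by_day, level, "inter")
        rec = recovery_pct(float(grp["measured"].mean()), 0.0, float(level))
        rows.append(
            {
                "level_ug_kg": level,
                "recovery_pct": rec,
                "intra_accuracy_pct": intra.accuracy_pct,
                "intra_rsd_pct": intra.rsd_pct,
                "inter_accuracy_pct": inter.accuracy_pct,
                "inter_rsd_pct": inter.rsd_pct,
            }
        )
    report = pd.DataFrame(rows)
    report.insert(0, "slope", curve.slope)
    report.insert(1, "intercept", curve.intercept)
    report.insert(2, "r_squared", curve.r_squared)
    report.insert(3, "lod_ug_kg", curve.lod)
    report.insert(4, "loq_ug_kg", curve.loq)
    return report
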