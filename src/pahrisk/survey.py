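"""Survey summaries for left-censored PAH4 concentration data.

Concentrations below the LOQ are substituted with zero (simple left-censoring
substitution; no likelihood-based imputation).  Summaries per commodity ×
compound are the mean ± sample SD, the median with quartiles Q1–Q3 by linear
interpolation of order statistics, and the detection rate (fraction of
samples at or above the LOQ).  Two PAH4 aggregates are exposed with distinct
semantics:

* :func:`four_pah_mean` — the arithmetic mean of the four compound values,
  the per-commodity summary column conventionally reported alongside the
  compound means;
* :func:`four_pah_sum` — the true sum, which is what the EU maximum level of
  50 µg/kg for the PAH4 set regulates.

Compliance with the EU maximum levels (10 µg/kg BaP, 50 µg/kg PAH4 sum) is
checked inclusively: a value exactly at the limit is compliant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .compounds import COMPOUNDS
from . import reference


@dataclass(frozen=True)
class SampleRecord:
    """One compound measurement on one commodity sample, after censoring."""

    commodity: str
    sample_id: str
    compound: str
    concentration: float  # µg/kg; 0 when censored
    censored: bool

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative after censoring")
        if self.censored and self.concentration != 0:
            raise ValueError("censored records must carry concentration 0")


@dataclass(frozen=True)
class RegulatoryLimits:
    """EU maximum levels for dried herbs and spices (µg/kg)."""

    bap_limit: float = reference.EU_BAP_LIMIT
    sum4_limit: float = reference.EU_SUM4_LIMIT

    def __post_init__(self) -> None:
        if self.bap_limit <= 0 or self.sum4_limit <= 0:
            raise ValueError("regulatory limits must be positive")


def censor_below_loq(
    values: Sequence[float], loq: float
) -> list[tuple[float, bool]]:
    """Replace values below the LOQ with zero, flagging them as censored.

    Idempotent: censored zeros stay censored zeros on reapplication.
    """
    if loq <= 0:
        raise ValueError("loq must be positive")
    return [(0.0, True) if v < loq else (float(v), False) for v in values]


def detection_rate(censored: Sequence[bool]) -> float:
    """Percent of records not censored (detected at or above the LOQ)."""
    flags = np.asarray(censored, dtype=bool)
    if flags.size == 0:
        raise ValueError("detection rate undefined on empty input")
    return 100.0 * float((~flags).mean())


def quartiles(values: Sequence[float]) -> tuple[float, float, float]:
    """Q1, median, Q3 by linear interpolation of order statistics."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("quartiles undefined on empty input")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75], method="linear")
    return float(q1), float(med), float(q3)


def four_pah_mean(means: Sequence[float]) -> float:
    """Mean of the four compound values (the reported PAH4 summary column)."""
    if len(means) != 4:
        raise ValueError("exactly four compound values required")
    if any(m < 0 for m in means):
        raise ValueError("compound values must be non-negative")
    return float(np.mean(means))


def four_pah_sum(values: Sequence[float]) -> float:
    """Sum of the four compound values (the quantity the EU limit regulates)."""
    if len(values) != 4:
        raise ValueError("exactly four compound values required")
    if any(v < 0 for v in values):
        raise ValueError("compound values must be non-negative")
    return float(np.sum(values))


def summarize(survey: pd.DataFrame) -> pd.DataFrame:
    """Per commodity × compound summary of a censored survey table.

    ``survey`` is the long schema (commodity, sample_id, compound,
    concentration, censored).  Returns one row per commodity × compound with
    mean, SD (n−1), median, Q1, Q3 (µg/kg) and detection rate (%).
    """
    if survey.empty:
        raise ValueError("empty survey")
    rows = []
    for (commodity, compound), grp in survey.groupby(
        ["commodity", "compound"], sort=False
    ):
        v = grp["concentration"].to_numpy(dtype=float)
        q1, med, q3 = quartiles(v)
        rows.append(
            {
                "commodity": commodity,
                "compound": compound,
                "n": len(v),
                "mean_ug_kg": float(v.mean()),
                "sd_ug_kg": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                "median_ug_kg": med,
                "q1_ug_kg": q1,
                "q3_ug_kg": q3,
                "detection_rate_pct": detection_rate(grp["censored"].to_numpy()),
            }
        )
    return pd.DataFrame(rows)


def commodity_aggregates(summary: pd.DataFrame) -> pd.DataFrame:
    """PAH4 aggregates per commodity from a per-compound summary table.

    Adds ``four_pah_mean_ug_kg`` (reported summary column) and
    ``four_pah_sum_ug_kg`` (regulatory quantity) computed from the four
    compound means.
    """
    rows = []
    for commodity, grp in summary.groupby("commodity", sort=False):
        means = grp.set_index("compound")["mean_ug_kg"]
        missing = set(COMPOUNDS) - set(means.index)
        if missing:
            raise ValueError(f"{commodity}: missing compounds {sorted(missing)}")
        four = [float(means[c]) for c in COMPOUNDS]
        rows.append(
            {
                "commodity": commodity,
                "four_pah_mean_ug_kg": four_pah_mean(four),
                "four_pah_sum_ug_kg": four_pah_sum(four),
                "bap_mean_ug_kg": float(means["BaP"]),
            }
        )
    return pd.DataFrame(rows)


def check_compliance(
    bap: float, sum4: float, limits: RegulatoryLimits | None = None
) -> dict[str, bool]:
    """EU maximum-level check; the boundary counts as compliant."""
    if bap < 0 or sum4 < 0:
        raise ValueError("concentrations must be non-negative")
    limits = limits or RegulatoryLimits()
    return {"bap_pass": bap <= limits.bap_limit, "sum4_pass": sum4 <= limits.sum4_limit}


def compliance_table(
    aggregates: pd.DataFrame, limits: RegulatoryLimits | None = None
) -> pd.DataFrame:
    """Per-commodity compliance flags against the EU maximum levels."""
    limits = limits or RegulatoryLimits()
    out = aggregates[["commodity"]].copy()
    flags = [
        check_compliance(b, s, limits)
        for b, s in zip(aggregates["bap_mean_ug_kg"], aggregates["four_pah_sum_ug_kg"])
    ]
    out["bap_pass"] = [f["bap_pass"] for f in flags]
    out["sum4_pass"] = [f["sum4_pass"] for f in flags]
    return out
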