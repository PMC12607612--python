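"""TEQ / EDI / MOE risk-characterization chain for dietary PAH exposure.

The chain converts surveyed concentrations into a public-health margin:

* **TEQ** (toxic equivalent quantity, µg/kg BaP-equivalent):
  ``TEQ = Σᵢ Cᵢ × TEFᵢ``, with TEFs expressing carcinogenic potency relative
  to BaP (TEF = 1).  Two indices are carried throughout: TEQ over BaP alone
  and TEQ over the full PAH4 set.
* **EDI** (estimated daily intake, ng/kg_bw/day):
  ``EDI = C × IR / BW`` with C the TEQ (µg/kg food ≡ ng/g food), IR the
  daily intake (g/day) and BW the body weight (kg).
* **MOE** (margin of exposure, dimensionless):
  ``MOE = BMDL₁₀ / EDI`` with BMDL₁₀ in mg/kg_bw/day converted to
  ng/kg_bw/day (× 10⁶).  MOE at or above 10⁴ is conventionally read as low
  public-health concern; the boundary is treated as low.
* **Critical intake** (g/day): the consumption at which the MOE falls to the
  threshold, ``IR* = BMDL₁₀ × 10⁶ × BW / (threshold × TEQ)``.

Unit conversions are centralized here: µg/kg of food is numerically ng/g of
food, and the single mg→ng factor of 10⁶ appears only in this module.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import pandas as pd

from .compounds import COMPOUNDS, DEFAULT_TEFS, UnknownCompoundError
from . import reference

MG_TO_NG = 1.0e6


class _UnboundedMOE:
    """Sentinel for the MOE at zero exposure: larger than any finite margin."""

    _instance: "_UnboundedMOE | None" = None

    def __new__(cls) -> "_UnboundedMOE":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # printed in reports
        return ">1e12"

    def __gt__(self, other: object) -> bool:
        return not isinstance(other, _UnboundedMOE)

    def __ge__(self, other: object) -> bool:
        return True

    def __lt__(self, other: object) -> bool:
        return False

    def __le__(self, other: object) -> bool:
        return isinstance(other, _UnboundedMOE)


UNBOUNDED_MOE = _UnboundedMOE()


@dataclass(frozen=True)
class TEFTable:
    """Toxic equivalency factors relative to BaP (which must carry TEF 1)."""

    tefs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TEFS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "tefs", dict(self.tefs))
        if any(v <= 0 for v in self.tefs.values()):
            raise ValueError("all TEFs must be positive")
        if self.tefs.get("BaP") != 1.0:
            raise ValueError("BaP is the reference compound and must have TEF 1")

    def __getitem__(self, compound: str) -> float:
        try:
            return self.tefs[compound]
        except KeyError:
            raise UnknownCompoundError(compound) from None


@dataclass(frozen=True)
class RiskParams:
    """Exposure-assessment parameters for one commodity scenario."""

    bmdl10_bap: float = reference.BMDL10_BAP  # mg/kg_bw/day
    bmdl10_sum4: float = reference.BMDL10_SUM4  # mg/kg_bw/day
    body_weight: float = reference.BODY_WEIGHT_KG  # kg
    moe_threshold: float = reference.MOE_THRESHOLD
    intake_mean: float = 1.0  # g/day
    intake_p95: float = 3.0  # g/day

    def __post_init__(self) -> None:
        for name in ("bmdl10_bap", "bmdl10_sum4", "body_weight", "moe_threshold",
                     "intake_mean", "intake_p95"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.intake_p95 < self.intake_mean:
            raise ValueError("intake_p95 must be at least intake_mean")


def compute_teq(
    concentrations: Mapping[str, float], tefs: TEFTable | None = None
) -> float:
    """TEF-weighted toxic equivalent (µg/kg BaP-equivalent): Σ Cᵢ × TEFᵢ.

    Pass BaP alone for the BaP index, or all four compounds for the PAH4
    index.
    """
    tefs = tefs or TEFTable()
    total = 0.0
    for compound, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {compound}")
        total += conc * tefs[compound]
    return total


def compute_edi(teq: float, intake: float, body_weight: float) -> float:
    """Estimated daily intake in ng/kg_bw/day.

    TEQ in µg/kg of food is numerically ng/g of food, so
    EDI = TEQ × intake(g/day) / body weight(kg) needs no further conversion.
    """
    if body_weight <= 0:
        raise ValueError("body_weight must be positive")
    if teq < 0 or intake < 0:
        raise ValueError("teq and intake must be non-negative")
    return teq * intake / body_weight


def compute_moe(bmdl10: float, edi: float) -> float | _UnboundedMOE:
    """Margin of exposure: BMDL₁₀ (mg/kg_bw/day → ng) over EDI (ng/kg_bw/day).

    Zero exposure yields the unbounded sentinel rather than a float infinity.
    """
    if bmdl10 <= 0:
        raise ValueError("bmdl10 must be positive")
    if edi < 0:
        raise ValueError("edi must be non-negative")
    if edi == 0:
        return UNBOUNDED_MOE
    return bmdl10 * MG_TO_NG / edi


def classify_moe(moe: float | _UnboundedMOE, threshold: float) -> str:
    """'low' concern iff MOE ≥ threshold (boundary inclusive), else 'elevated'."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if isinstance(moe, _UnboundedMOE) or moe >= threshold:
        return "low"
    return "elevated"


def critical_intake(
    teq: float, bmdl10: float, body_weight: float, threshold: float
) -> float:
    """Daily consumption (g/day) at which the MOE equals the threshold."""
    if teq <= 0:
        raise ValueError("critical intake undefined for zero TEQ")
    if min(bmdl10, body_weight, threshold) <= 0:
        raise ValueError("bmdl10, body_weight and threshold must be positive")
    return bmdl10 * MG_TO_NG * body_weight / (threshold * teq)


@dataclass(frozen=True)
class RiskResult:
    """One commodity's row of the risk table: TEQ, EDI, MOE and concern."""

    commodity: str
    teq_bap: float
    teq_sum4: float
    edi: dict[tuple[str, str], float]  # (index, scenario) → ng/kg_bw/day
    moe: dict[tuple[str, str], float | _UnboundedMOE]
    concern: dict[tuple[str, str], str]
    critical_intake_bap: float | None  # g/day; None when TEQ is zero
    critical_intake_sum4: float | None


_INDICES = ("bap", "sum4")
_SCENARIOS = ("mean", "p95")


def assess_commodity(
    commodity: str,
    compound_means: Mapping[str, float],
    params: RiskParams,
    tefs: TEFTable | None = None,
) -> RiskResult:
    """Run the full TEQ → EDI → MOE chain for one commodity.

    ``compound_means`` maps each PAH4 compound to its mean concentration
    (µg/kg).  The 2 × 2 grid covers (BaP, PAH4) indices × (mean, P95) intake
    scenarios.
    """
    tefs = tefs or TEFTable()
    missing = set(COMPOUNDS) - set(compound_means)
    if missing:
        raise ValueError(f"{commodity}: missing compounds {sorted(missing)}")
    teq = {
        "bap": compute_teq({"BaP": compound_means["BaP"]}, tefs),
        "sum4": compute_teq({c: compound_means[c] for c in COMPOUNDS}, tefs),
    }
    bmdl = {"bap": params.bmdl10_bap, "sum4": params.bmdl10_sum4}
    intake = {"mean": params.intake_mean, "p95": params.intake_p95}
    edi, moe, concern = {}, {}, {}
    for idx in _INDICES:
        for sc in _SCENARIOS:
            e = compute_edi(teq[idx], intake[sc], params.body_weight)
            m = compute_moe(bmdl[idx], e)
            edi[(idx, sc)] = e
            moe[(idx, sc)] = m
            concern[(idx, sc)] = classify_moe(m, params.moe_threshold)
    return RiskResult(
        commodity=commodity,
        teq_bap=teq["bap"],
        teq_sum4=teq["sum4"],
        edi=edi,
        moe=moe,
        concern=concern,
        critical_intake_bap=(
            critical_intake(teq["bap"], bmdl["bap"], params.body_weight, params.moe_threshold)
            if teq["bap"] > 0
            else None
        ),
        critical_intake_sum4=(
            critical_intake(teq["sum4"], bmdl["sum4"], params.body_weight, params.moe_threshold)
            if teq["sum4"] > 0
            else None
        ),
    )


def run_risk_table(
    compound_means: Mapping[str, Mapping[str, float]],
    params_by_commodity: Mapping[str, RiskParams],
    tefs: TEFTable | None = None,
) -> list[RiskResult]:
    """Assess every commodity; requires one RiskParams entry per commodity."""
    results = []
    for commodity, means in compound_means.items():
        if commodity not in params_by_commodity:
            raise KeyError(f"no risk parameters for commodity {commodity!r}")
        results.append(
            assess_commodity(commodity, means, params_by_commodity[commodity], tefs)
        )
    return results


def risk_table_frame(results: list[RiskResult]) -> pd.DataFrame:
    """Flatten risk results into the report table (one row per commodity)."""
    rows = []
    for r in results:
        row: dict[str, object] = {
            "commodity": r.commodity,
            "teq_bap_ug_kg": r.teq_bap,
            "teq_sum4_ug_kg": r.teq_sum4,
        }
        for idx in _INDICES:
            for sc in _SCENARIOS:
                row[f"edi_{idx}_{sc}_ng_kgbw_day"] = r.edi[(idx, sc)]
                row[f"moe_{idx}_{sc}"] = repr(r.moe[(idx, sc)]) if isinstance(
                    r.moe[(idx, sc)], _UnboundedMOE
                ) else r.moe[(idx, sc)]
                row[f"concern_{idx}_{sc}"] = r.concern[(idx, sc)]
        row["critical_intake_bap_g_day"] = r.critical_intake_bap
        row["critical_intake_sum4_g_day"] = r.critical_intake_sum4
        rows.append(row)
    return pd.DataFrame(rows)


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero (report formatting convention)."""
    import math

    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
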