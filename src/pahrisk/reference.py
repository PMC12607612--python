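"""Published reference values for the South Korean herb-and-spice PAH4 survey.

These tables transcribe the reported results of a GC-MS market survey of 110
herb and spice products (10 commercial samples each of 6 spices and 5 herbs)
sold in South Korea.  They serve two roles in this package:

* as *inputs* to the risk-characterization chain — the per-commodity mean
  concentrations feed the TEQ/EDI/MOE computations, exactly as the survey's
  own risk assessment used them;
* as *calibration* for the synthetic-data generator, whose default study
  conditions (detection probabilities, concentration scales, instrument
  response) are taken from these values.

Units: concentrations in µg/kg of dry product; calibration slopes in
area-ratio per (µg/kg); LOD/LOQ in µg/kg.
"""

from __future__ import annotations

import pandas as pd

SPICES: tuple[str, ...] = (
    "Mustard",
    "Nutmeg",
    "Black pepper",
    "Sichuan pepper",
    "Cinnamon",
    "Turmeric",
)
HERBS: tuple[str, ...] = ("Basil", "Oregano", "Parsley", "Rosemary", "Bay leaves")
COMMODITIES: tuple[str, ...] = SPICES + HERBS

#: Which validation matrix (calibration/LOQ set) applies to each commodity.
MATRIX_OF: dict[str, str] = {c: "spice" for c in SPICES} | {c: "herb" for c in HERBS}

# ---------------------------------------------------------------------------
# Method validation: internal-standard calibration per matrix and compound.
# slope/intercept describe the analyte/IS area-ratio response; LOD and LOQ
# follow the S/N = 3.3 and S/N = 10 conventions.
# ---------------------------------------------------------------------------
CALIBRATION: dict[tuple[str, str], dict[str, float]] = {
    ("spice", "BaA"): dict(slope=0.0085, intercept=-0.0013, r2=1.000, lod=0.08, loq=0.24),
    ("spice", "CHR"): dict(slope=0.0115, intercept=0.0010, r2=0.998, lod=0.15, loq=0.46),
    ("spice", "BbF"): dict(slope=0.0158, intercept=0.0037, r2=0.999, lod=0.18, loq=0.55),
    ("spice", "BaP"): dict(slope=0.0109, intercept=0.0016, r2=0.999, lod=0.12, loq=0.37),
    ("herb", "BaA"): dict(slope=0.0082, intercept=-0.0014, r2=0.999, lod=0.17, loq=0.51),
    ("herb", "CHR"): dict(slope=0.0113, intercept=0.0010, r2=1.000, lod=0.11, loq=0.32),
    ("herb", "BbF"): dict(slope=0.0150, intercept=0.0021, r2=1.000, lod=0.13, loq=0.41),
    ("herb", "BaP"): dict(slope=0.0097, intercept=0.0018, r2=0.999, lod=0.15, loq=0.46),
}

CALIBRATION_LEVELS: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0)

#: Spike-recovery means (%) per matrix, compound and spike level (µg/kg).
RECOVERY_PCT: dict[tuple[str, str], dict[float, float]] = {
    ("spice", "BaA"): {1: 88.6, 2: 98.4, 5: 101.0, 10: 116.2, 20: 116.5},
    ("spice", "CHR"): {1: 102.1, 2: 98.6, 5: 107.6, 10: 103.3, 20: 98.1},
    ("spice", "BbF"): {1: 96.3, 2: 99.9, 5: 93.0, 10: 97.7, 20: 93.5},
    ("spice", "BaP"): {1: 95.6, 2: 96.1, 5: 100.0, 10: 112.2, 20: 109.0},
    ("herb", "BaA"): {1: 109.3, 2: 97.2, 5: 94.2, 10: 104.1, 20: 112.9},
    ("herb", "CHR"): {1: 108.3, 2: 101.1, 5: 97.7, 10: 97.6, 20: 96.5},
    ("herb", "BbF"): {1: 94.5, 2: 90.7, 5: 85.0, 10: 89.4, 20: 89.0},
    ("herb", "BaP"): {1: 91.4, 2: 97.7, 5: 95.0, 10: 96.4, 20: 99.8},
}

# ---------------------------------------------------------------------------
# Survey summaries: per-commodity mean ± SD (µg/kg, censored values counted
# as zero), the reported PAH4 aggregate column (the mean of the four compound
# means), and per-compound detection rates (%).
# ---------------------------------------------------------------------------
_MEANS_ROWS = [
    # commodity,        BaA,   CHR,   BbF,   BaP
    ("Mustard", 0.18, 0.42, 0.15, 0.29),
    ("Nutmeg", 1.05, 1.09, 0.00, 0.12),
    ("Black pepper", 1.86, 3.13, 0.65, 0.93),
    ("Sichuan pepper", 1.36, 2.85, 1.61, 1.37),
    ("Cinnamon", 3.39, 6.98, 2.78, 6.18),
    ("Turmeric", 0.39, 0.20, 0.00, 0.09),
    ("Basil", 0.83, 0.93, 1.30, 1.75),
    ("Oregano", 0.32, 1.10, 3.18, 7.13),
    ("Parsley", 0.35, 1.76, 0.00, 0.48),
    ("Rosemary", 0.07, 0.36, 0.61, 0.77),
    ("Bay leaves", 5.12, 7.61, 0.88, 0.79),
]

_SD_ROWS = [
    ("Mustard", 0.45, 1.12, 0.49, 0.92),
    ("Nutmeg", 0.81, 0.95, 0.00, 0.28),
    ("Black pepper", 1.98, 2.70, 1.86, 1.56),
    ("Sichuan pepper", 1.87, 4.66, 2.11, 2.44),
    ("Cinnamon", 4.86, 5.27, 4.30, 3.46),
    ("Turmeric", 0.44, 0.42, 0.00, 0.20),
    ("Basil", 0.58, 0.83, 2.46, 2.84),
    ("Oregano", 0.50, 1.31, 3.26, 6.68),
    ("Parsley", 0.50, 1.77, 0.00, 1.52),
    ("Rosemary", 0.22, 0.69, 1.03, 2.43),
    ("Bay leaves", 5.33, 6.50, 1.07, 1.05),
]

#: Reported PAH4 aggregate column (mean of the four compound means, µg/kg).
SUM4_MEAN_REPORTED: dict[str, float] = {
    "Mustard": 0.26,
    "Nutmeg": 0.56,
    "Black pepper": 1.64,
    "Sichuan pepper": 1.80,
    "Cinnamon": 4.83,
    "Turmeric": 0.17,
    "Basil": 1.23,
    "Oregano": 2.94,
    "Parsley": 0.65,
    "Rosemary": 0.45,
    "Bay leaves": 3.60,
}

_DETECTION_ROWS = [
    ("Mustard", 20.0, 20.0, 10.0, 10.0),
    ("Nutmeg", 80.0, 70.0, 0.0, 20.0),
    ("Black pepper", 80.0, 90.0, 20.0, 60.0),
    ("Sichuan pepper", 60.0, 60.0, 40.0, 40.0),
    ("Cinnamon", 80.0, 90.0, 70.0, 90.0),
    ("Turmeric", 50.0, 20.0, 0.0, 20.0),
    ("Basil", 80.0, 70.0, 40.0, 40.0),
    ("Oregano", 40.0, 50.0, 70.0, 70.0),
    ("Parsley", 40.0, 70.0, 0.0, 10.0),
    ("Rosemary", 10.0, 30.0, 30.0, 10.0),
    ("Bay leaves", 90.0, 100.0, 60.0, 40.0),
]

#: Reported per-commodity toxic equivalents (µg/kg BaP-equivalent):
#: TEQ_BaP (BaP alone) and TEQ over the full PAH4 set.
TEQ_REPORTED: dict[str, tuple[float, float]] = {
    "Mustard": (0.29, 0.33),
    "Nutmeg": (0.12, 0.24),
    "Black pepper": (0.93, 1.22),
    "Sichuan pepper": (1.37, 1.70),
    "Cinnamon": (6.18, 6.87),
    "Turmeric": (0.09, 0.14),
    "Basil": (1.75, 1.98),
    "Oregano": (7.13, 7.50),
    "Parsley": (0.48, 0.54),
    "Rosemary": (0.77, 0.84),
    "Bay leaves": (0.79, 1.46),
}

N_PER_COMMODITY: int = 10

# Risk-characterization parameters of the survey's exposure assessment.
BMDL10_BAP: float = 0.07  # mg/kg_bw/day, BaP index
BMDL10_SUM4: float = 0.34  # mg/kg_bw/day, PAH4 index
BODY_WEIGHT_KG: float = 66.83  # mean adult body weight
MOE_THRESHOLD: float = 1e4  # MOE at/above this → low public-health concern

# EU maximum levels for dried herbs and spices.
EU_BAP_LIMIT: float = 10.0  # µg/kg
EU_SUM4_LIMIT: float = 50.0  # µg/kg


def _frame(rows: list[tuple]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["commodity", "BaA", "CHR", "BbF", "BaP"])
    return df.set_index("commodity")


def survey_means() -> pd.DataFrame:
    """Per-commodity mean concentrations (µg/kg), censored values as zero."""
    return _frame(_MEANS_ROWS)


def survey_sds() -> pd.DataFrame:
    """Per-commodity concentration standard deviations (µg/kg, n−1)."""
    return _frame(_SD_ROWS)


def detection_rates() -> pd.DataFrame:
    """Per-commodity detection rates (%), detection meaning ≥ LOQ."""
    return _frame(_DETECTION_ROWS)


def loq_of(commodity: str, compound: str) -> float:
    """LOQ (µg/kg) applicable to a commodity via its validation matrix."""
    return CALIBRATION[(MATRIX_OF[commodity], compound)]["loq"]
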