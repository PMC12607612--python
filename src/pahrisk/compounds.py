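"""Compound vocabulary for the EFSA PAH4 marker set.

The four marker polycyclic aromatic hydrocarbons (PAH4) recommended by EFSA
for food surveillance: benz[a]anthracene (BaA), chrysene (CHR),
benzo[b]fluoranthene (BbF) and benzo[a]pyrene (BaP).  BaP is the reference
compound of the toxic-equivalency scheme (TEF = 1); the other three are
weighted by their carcinogenic potency relative to BaP.

The vocabulary is deliberately small but extensible: any mapping that assigns
a positive TEF to each compound it covers (e.g. the EFSA PAH8 set) can be
passed wherever a TEF table is expected.
"""

from __future__ import annotations

COMPOUNDS: tuple[str, ...] = ("BaA", "CHR", "BbF", "BaP")

#: Toxic equivalency factors relative to benzo[a]pyrene (dimensionless).
DEFAULT_TEFS: dict[str, float] = {"BaA": 0.1, "CHR": 0.01, "BbF": 0.1, "BaP": 1.0}

FULL_NAMES: dict[str, str] = {
    "BaA": "benz[a]anthracene",
    "CHR": "chrysene",
    "BbF": "benzo[b]fluoranthene",
    "BaP": "benzo[a]pyrene",
}


class UnknownCompoundError(ValueError):
    """Raised when a compound label is outside the known vocabulary."""

    def __init__(self, label: object) -> None:
        super().__init__(
            f"unknown compound {label!r}; valid labels are {', '.join(COMPOUNDS)}"
        )


def validate_compound(label: str) -> str:
    if label not in COMPOUNDS:
        raise UnknownCompoundError(label)
    return label
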