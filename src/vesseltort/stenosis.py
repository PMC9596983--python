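"""Percent in-stent stenosis and ISS severity classification.

The loss rate of the stented lumen is 100 * (1 - vessel_d / stent_d), where
vessel_d is the narrowest in-stent vessel diameter at follow-up and stent_d
the stent diameter at the same position.  ISS means narrowing strictly
greater than 25%; narrowing beyond 50% is graded severe (severe cases still
count as ISS in binary analyses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "StenosisMeasurement",
    "stenosis_percent",
    "classify_iss",
    "annotate_stenosis",
]

ISS_THRESHOLD = 25.0
SEVERE_THRESHOLD = 50.0


@dataclass(frozen=True)
class StenosisMeasurement:
    vessel_diameter: float
    stent_diameter: float
    percent_stenosis: float
    iss_class: str

    @property
    def iss(self) -> int:
        """Binary ISS indicator (severe counts as ISS)."""
        return int(self.iss_class in ("ISS", "severe"))


def stenosis_percent(vessel_d: float, stent_d: float) -> float:
    """Percent diameter loss, 100 * (1 - vessel_d / stent_d).

    Negative when the vessel measures wider than the stent; such values are
    returned as-is (they flag a measurement worth re-checking) rather than
    clamped to zero.
    """
    if not (vessel_d > 0 and stent_d > 0):
        raise ValueError("diameters must be positive")
    return 100.0 * (1.0 - vessel_d / stent_d)


def classify_iss(percent: float) -> str:
    """Severity class for a percent-stenosis value.

    <= 25 -> "none" (the definition is strictly greater than 25%),
    25 < p <= 50 -> "ISS", > 50 -> "severe".
    """
    if not math.isfinite(percent):
        raise ValueError("percent must be finite")
    if percent > SEVERE_THRESHOLD:
        return "severe"
    if percent > ISS_THRESHOLD:
        return "ISS"
    return "none"


def measure(vessel_d: float, stent_d: float) -> StenosisMeasurement:
    pct = stenosis_percent(vessel_d, stent_d)
    return StenosisMeasurement(vessel_d, stent_d, pct, classify_iss(pct))


def annotate_stenosis(table: pd.DataFrame) -> pd.DataFrame:
    """Append percent_stenosis, iss_class and binary iss columns.

    Expects columns ``vessel_diameter_mm`` and ``stent_diameter_mm``.
    """
    for col in ("vessel_diameter_mm", "stent_diameter_mm"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    out = table.copy()
    pct = [
        stenosis_percent(v, s)
        for v, s in zip(out["vessel_diameter_mm"], out["stent_diameter_mm"])
    ]
    out["percent_stenosis"] = pct
    out["iss_class"] = [classify_iss(p) for p in pct]
    out["iss"] = [int(p > ISS_THRESHOLD) for p in pct]
    return out
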