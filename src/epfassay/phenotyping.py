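"""Hemocytometer arithmetic, thermal-biology profiles and enzyme grading."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .data_model import EnzymeAssay, TemperatureAssay

#: Improved-Neubauer large-square volume (1 mm^2 x 0.1 mm depth) in ml.
NEUBAUER_SQUARE_ML = 1e-4

#: Diameter of the agar plug used to seed radial-growth plates, in mm.
PLUG_DIAMETER_MM = 6.0

_ENZYME_SYMBOLS = {"-": 0, "−": 0, "+": 1, "++": 2, "+++": 3}
_CONTROL_TEMP = 28.0


def hemocytometer_concentration(
    mean_count_per_square: float,
    dilution_factor: float,
    square_volume_ml: float = NEUBAUER_SQUARE_ML,
) -> float:
    """Spore concentration (spores/ml) from a hemocytometer count.

    concentration = mean count per large square * dilution / square volume.
    """
    if mean_count_per_square < 0 or dilution_factor < 0:
        raise ValueError("counts and dilution must be non-negative")
    if square_volume_ml <= 0:
        raise ValueError("square_volume_ml must be positive")
    return mean_count_per_square * dilution_factor / square_volume_ml


def cadaver_spore_yield(concentration: float, suspension_volume_ml: float = 1.0) -> float:
    """Total spores recovered per larval cadaver suspended in the given volume."""
    if concentration < 0 or suspension_volume_ml < 0:
        raise ValueError("inputs must be non-negative")
    return concentration * suspension_volume_ml


@dataclass
class TemperatureProfile:
    isolate_id: str
    germination_pct: dict[float, float] = field(default_factory=dict)
    radial_diameter_mm: dict[float, float] = field(default_factory=dict)
    radial_net_growth_mm: dict[float, float] = field(default_factory=dict)
    sporulation_start_day: dict[float, Optional[float]] = field(default_factory=dict)
    optimum_temperature: Optional[float] = None


def temperature_profile(assays: Sequence[TemperatureAssay]) -> TemperatureProfile:
    """Pivot per-temperature assays into one isolate's thermal profile.

    The optimum temperature is the argmax of germination, ties broken toward
    the 28 degC control; it is undefined with fewer than two temperatures.
    Net radial growth subtracts the 6-mm seed plug.
    """
    if not assays:
        raise ValueError("no temperature assays supplied")
    ids = {a.isolate_id for a in assays}
    if len(ids) > 1:
        raise ValueError(f"assays mix isolates: {sorted(ids)}")
    prof = TemperatureProfile(isolate_id=ids.pop())
    for a in sorted(assays, key=lambda a: a.temperature):
        prof.germination_pct[a.temperature] = a.germination_pct
        prof.radial_diameter_mm[a.temperature] = a.radial_diameter_mm
        prof.radial_net_growth_mm[a.temperature] = max(a.radial_diameter_mm - PLUG_DIAMETER_MM, 0.0)
        prof.sporulation_start_day[a.temperature] = a.sporulation_start_day
    if len(prof.germination_pct) >= 2:
        best = max(prof.germination_pct.values())
        candidates = [t for t, g in prof.germination_pct.items() if g == best]
        prof.optimum_temperature = (
            _CONTROL_TEMP if _CONTROL_TEMP in candidates else min(candidates)
        )
    return prof


def enzyme_grade(symbolic: str) -> int:
    """Ordinal 0-3 encoding of the clear-zone symbols -, +, ++, +++."""
    try:
        return _ENZYME_SYMBOLS[symbolic.strip()]
    except KeyError:
        raise ValueError(f"unknown enzyme grade symbol {symbolic!r}") from None


def enzyme_symbol(grade: int) -> str:
    """Inverse of :func:`enzyme_grade`."""
    symbols = {0: "-", 1: "+", 2: "++", 3: "+++"}
    if grade not in symbols:
        raise ValueError(f"grade must be 0-3, got {grade}")
    return symbols[grade]


def grade_assay(isolate_id: str, enzyme: str, symbolic: str) -> EnzymeAssay:
    return EnzymeAssay(isolate_id=isolate_id, enzyme=enzyme, grade=enzyme_grade(symbolic))
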