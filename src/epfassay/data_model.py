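"""Domain types for entomopathogen bioassay records.

Every record type validates its own invariants on construction (pydantic),
so downstream stages can assume clean data. Daily death counts are stored
cumulatively: ``deaths_by_day[d-1]`` is the number dead by the end of day
``d`` (days are 1-based).
"""

from __future__ import annotations

from enum import Enum
from typing import Optional, Sequence

from pydantic import BaseModel, Field, field_validator, model_validator


class SoilSource(str, Enum):
    cropland = "cropland"
    grassland = "grassland"
    forest = "forest"
    other = "other"


class Host(str, Enum):
    galleria = "galleria"
    tuta = "tuta"


class IsolateRecord(BaseModel):
    """Identity and provenance of one fungal isolate."""

    isolate_id: str = Field(min_length=1)
    source: SoilSource
    species_label: str = ""
    accession: Optional[str] = None


class GerminationAssay(BaseModel):
    """Conidial viability count for one replicate plate.

    The standard protocol inspects 100 spores per replicate, so the
    germinated fraction is directly a percentage.
    """

    isolate_id: str = Field(min_length=1)
    replicate: int = Field(ge=1)
    temperature: float = 25.0
    n_counted: int = Field(default=100, ge=1)
    n_germinated: int = Field(ge=0)

    @model_validator(mode="after")
    def _germinated_within_counted(self) -> "GerminationAssay":
        if self.n_germinated > self.n_counted:
            raise ValueError(
                f"n_germinated ({self.n_germinated}) exceeds n_counted ({self.n_counted})"
            )
        return self


class SporulationAssay(BaseModel):
    """First day conidia appear on a plate culture (DPCS), per replicate."""

    isolate_id: str = Field(min_length=1)
    replicate: int = Field(ge=1)
    temperature: float = 28.0
    dpcs_day: Optional[float] = Field(default=None, gt=0)
    window_end_day: float = Field(default=20.0, gt=0)

    @model_validator(mode="after")
    def _dpcs_within_window(self) -> "SporulationAssay":
        if self.dpcs_day is not None and not (1.0 <= self.dpcs_day <= self.window_end_day):
            raise ValueError(
                f"dpcs_day ({self.dpcs_day}) outside [1, {self.window_end_day}]"
            )
        return self

    @property
    def censored(self) -> bool:
        """True when the isolate never sporulated within the window."""
        return self.dpcs_day is None


class MortalityAssay(BaseModel):
    """Cumulative daily deaths of exposed larvae for one replicate.

    ``dose`` is spores per ml; ``None`` marks a fixed-dose screening assay
    (1e7 spores/ml implied by the screening protocol). ``dose == 0`` marks
    an untreated control replicate.
    """

    isolate_id: str = Field(min_length=1)
    host: Host
    instar: int = Field(default=3, ge=1)
    dose: Optional[float] = Field(default=None, ge=0)
    replicate: int = Field(ge=1)
    n_exposed: int = Field(ge=1)
    deaths_by_day: tuple[int, ...]
    window_days: int = Field(ge=1)

    @field_validator("deaths_by_day", mode="before")
    @classmethod
    def _as_tuple(cls, v: Sequence[int]) -> tuple[int, ...]:
        return tuple(int(x) for x in v)

    @model_validator(mode="after")
    def _valid_series(self) -> "MortalityAssay":
        d = self.deaths_by_day
        if len(d) != self.window_days:
            raise ValueError(
                f"deaths_by_day length {len(d)} != window_days {self.window_days}"
            )
        if any(x < 0 for x in d):
            raise ValueError("negative death count")
        if any(b < a for a, b in zip(d, d[1:])):
            raise ValueError("non-monotone cumulative deaths")
        if d and d[-1] > self.n_exposed:
            raise ValueError(
                f"final deaths ({d[-1]}) exceed n_exposed ({self.n_exposed})"
            )
        return self

    @property
    def final_deaths(self) -> int:
        return self.deaths_by_day[-1]

    @classmethod
    def from_incremental(cls, *, deaths_per_day: Sequence[int], **kwargs) -> "MortalityAssay":
        """Build from per-day (incremental) death counts, converting to cumulative."""
        cum, total = [], 0
        for x in deaths_per_day:
            total += int(x)
            cum.append(total)
        return cls(deaths_by_day=tuple(cum), **kwargs)


class TemperatureAssay(BaseModel):
    """Thermal-biology measurements for one isolate at one temperature."""

    isolate_id: str = Field(min_length=1)
    temperature: float
    germination_pct: float = Field(ge=0, le=100)
    radial_diameter_mm: float = Field(default=0.0, ge=0)
    sporulation_start_day: Optional[float] = Field(default=None, gt=0)
    censor_day: float = Field(default=25.0, gt=0)

    @property
    def sporulation_censored(self) -> bool:
        return self.sporulation_start_day is None


class EnzymeAssay(BaseModel):
    """Ordinal clear-zone grade (0-3 encoding -, +, ++, +++) for one enzyme."""

    isolate_id: str = Field(min_length=1)
    enzyme: str
    grade: int = Field(ge=0, le=3)

    @field_validator("enzyme")
    @classmethod
    def _known_enzyme(cls, v: str) -> str:
        allowed = {"lipase", "protease", "chitinase"}
        if v not in allowed:
            raise ValueError(f"unknown enzyme {v!r}; expected one of {sorted(allowed)}")
        return v
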