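"""Biological Efficacy Index (BEI) screening of fungal isolates.

The BEI combines three culture/bioassay traits of an entomopathogenic
isolate into a single percentage used to rank and select candidates:

* SG  — spore germination percentage (conidial viability),
* RSR — relative sporulation rate, window length / first sporulation day,
* LM  — host-larva mortality percentage over the screening window.

With default weights (37, 13, 50) the index is

    BEI = 0.37*SG + 0.13*RSR + 0.50*LM

i.e. the published weights act as percentage coefficients on SG and LM
(both on the 0-100 scale) and on RSR on its raw ~1-2 scale. Isolates with
BEI strictly above the screening threshold (default 80) are selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .data_model import GerminationAssay, MortalityAssay, SporulationAssay

DEFAULT_WEIGHTS: tuple[float, float, float] = (37.0, 13.0, 50.0)
DEFAULT_THRESHOLD: float = 80.0


@dataclass
class ScreeningResult:
    """Per-isolate screening traits, index and classification."""

    isolate_id: str
    sg_pct: float
    rsr: Optional[float]
    lm_pct: float
    bei_pct: Optional[float]
    bei_group: str = "below"
    selected: bool = False
    efficacy: str = field(default="", compare=False)


def germination_percent(assays: Sequence[GerminationAssay]) -> float:
    """Mean germination percentage over replicates of one isolate."""
    if not assays:
        raise ValueError("no germination assays supplied")
    ids = {a.isolate_id for a in assays}
    if len(ids) > 1:
        raise ValueError(f"assays mix isolates: {sorted(ids)}")
    pcts = [100.0 * a.n_germinated / a.n_counted for a in assays]
    return sum(pcts) / len(pcts)


def relative_sporulation_rate(dpcs_day: Optional[float], window_end_day: float = 20.0) -> Optional[float]:
    """RSR = experiment window length / first plate-sporulation day.

    Returns ``None`` (censored) when the isolate never sporulated within the
    window; raises for non-positive days.
    """
    if dpcs_day is None:
        return None
    if dpcs_day <= 0:
        raise ValueError(f"dpcs_day must be positive, got {dpcs_day}")
    if dpcs_day > window_end_day:
        return None
    return window_end_day / dpcs_day


def mortality_percent(assays: Sequence[MortalityAssay], day: Optional[int] = None) -> float:
    """Mean percent mortality over replicates, cumulative to ``day``.

    ``day`` defaults to the end of the observation window.
    """
    if not assays:
        raise ValueError("no mortality assays supplied")
    pcts = []
    for a in assays:
        d = a.window_days if day is None else day
        if not (1 <= d <= a.window_days):
            raise ValueError(f"day {d} outside window [1, {a.window_days}]")
        pcts.append(100.0 * a.deaths_by_day[d - 1] / a.n_exposed)
    return sum(pcts) / len(pcts)


def bei(
    sg_pct: float,
    rsr: float,
    lm_pct: float,
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
) -> float:
    """Biological Efficacy Index in percent.

    Weights are percentage coefficients: ``(w_sg/100)*SG + (w_rsr/100)*RSR +
    (w_lm/100)*LM``. SG and LM must be on the 0-100 scale; RSR enters on its
    raw ratio scale.
    """
    if not (0.0 <= sg_pct <= 100.0):
        raise ValueError(f"sg_pct {sg_pct} outside [0, 100]")
    if not (0.0 <= lm_pct <= 100.0):
        raise ValueError(f"lm_pct {lm_pct} outside [0, 100]")
    if rsr < 0:
        raise ValueError(f"rsr must be non-negative, got {rsr}")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    w_sg, w_rsr, w_lm = weights
    return (w_sg / 100.0) * sg_pct + (w_rsr / 100.0) * rsr + (w_lm / 100.0) * lm_pct


def bei_group(bei_pct: float) -> str:
    """BEI group label: G1 (> 85), G2 (83, 85], G3 [80, 83], else 'below'.

    85.0 falls in G2 and the lower boundaries are closed, matching the
    published group assignments of the boundary isolates.
    """
    if not math.isfinite(bei_pct):
        raise ValueError("bei_pct must be finite")
    if bei_pct > 85.0:
        return "G1"
    if bei_pct > 83.0:
        return "G2"
    if bei_pct >= 80.0:
        return "G3"
    return "below"


def efficacy_class(lm_pct: float) -> str:
    """Mortality efficacy class: LE (< 70), ME [70, 80), HE (>= 80)."""
    if not (0.0 <= lm_pct <= 100.0):
        raise ValueError(f"lm_pct {lm_pct} outside [0, 100]")
    if lm_pct < 70.0:
        return "LE"
    if lm_pct < 80.0:
        return "ME"
    return "HE"


def screen(
    results: Sequence[ScreeningResult],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ScreeningResult]:
    """Select isolates with BEI strictly above ``threshold``.

    Returns the selected subset sorted by BEI descending and sets the
    ``selected`` flag on every input result (False for censored/missing BEI).
    """
    if not (0.0 < threshold < 100.0):
        raise ValueError(f"threshold {threshold} outside (0, 100)")
    for r in results:
        r.selected = r.bei_pct is not None and r.bei_pct > threshold
    chosen = [r for r in results if r.selected]
    chosen.sort(key=lambda r: (-r.bei_pct, r.isolate_id))
    return chosen


def score_isolate(
    isolate_id: str,
    germination: Sequence[GerminationAssay],
    sporulation: Sequence[SporulationAssay],
    mortality: Sequence[MortalityAssay],
    weights: tuple[float, float, float] = DEFAULT_WEIGHTS,
    window_end_day: float = 20.0,
) -> ScreeningResult:
    """Assemble one isolate's ScreeningResult from its raw assay records.

    DPCS is averaged over uncensored replicates before the RSR ratio is
    taken; a fully censored isolate gets a missing RSR and BEI.
    """
    sg = germination_percent(germination)
    days = [s.dpcs_day for s in sporulation if s.dpcs_day is not None]
    rsr = relative_sporulation_rate(sum(days) / len(days) if days else None, window_end_day)
    lm = mortality_percent(mortality)
    b = bei(sg, rsr, lm, weights) if rsr is not None else None
    return ScreeningResult(
        isolate_id=isolate_id,
        sg_pct=sg,
        rsr=rsr,
        lm_pct=lm,
        bei_pct=b,
        bei_group=bei_group(b) if b is not None else "below",
        efficacy=efficacy_class(lm),
    )
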