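"""Control-mortality correction and median-lethal-time (LT50) estimation.

LT50 is the time by which half of the exposed larvae have died at a fixed
dose. The default estimator interpolates the day on which each replicate's
cumulative mortality curve crosses 50% and averages over replicates;
replicates that never reach 50% within the observation window are censored
and excluded (but counted). A probit-on-log-time fit of the daily death
increments is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .data_model import MortalityAssay

CENSORED = None  # a censored replicate is a value, not an error


@dataclass
class LTEstimate:
    isolate_id: str
    dose: Optional[float]
    per_replicate: list[Optional[float]]
    mean: Optional[float]
    se: Optional[float]
    n_censored: int
    method: str = "interpolation"


def abbott(treated_pct: float, control_pct: float, clamp: bool = False) -> float:
    """Abbott-corrected mortality: 100 * (T - C) / (100 - C).

    Negative results (treatment below control) are returned as-is unless
    ``clamp`` is set; a control mortality of 100% leaves the correction
    undefined and raises.
    """
    if not (0.0 <= treated_pct <= 100.0):
        raise ValueError(f"treated_pct {treated_pct} outside [0, 100]")
    if not (0.0 <= control_pct <= 100.0):
        raise ValueError(f"control_pct {control_pct} outside [0, 100]")
    if control_pct == 100.0:
        raise ValueError("undefined correction: control mortality is 100%")
    corrected = 100.0 * (treated_pct - control_pct) / (100.0 - control_pct)
    return max(corrected, 0.0) if clamp else corrected


def cumulative_mortality_series(assay: MortalityAssay) -> np.ndarray:
    """Daily cumulative mortality proportions, non-decreasing in [0, 1]."""
    return np.asarray(assay.deaths_by_day, dtype=float) / assay.n_exposed


def lt50_replicate(
    series: Sequence[float], method: str = "interpolation"
) -> Optional[float]:
    """LT50 (days) of one replicate's cumulative-mortality series.

    interpolation
        Linear interpolation of the day at which the series crosses 0.5;
        the series is anchored at 0 mortality at day 0, so a crossing on
        day 1 is clipped to 1. Never reaching 0.5 -> censored (``None``).
    probit_time
        MLE of Phi(a + b*log10 t) on the daily death increments (survivors
        past the window treated as right-censored); LT50 = 10^(-a/b).
    """
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    if np.any(s < 0) or np.any(s > 1) or np.any(np.diff(s) < -1e-12):
        raise ValueError("series must be non-decreasing proportions in [0, 1]")
    if method == "interpolation":
        return _lt50_interpolate(s)
    if method == "probit_time":
        return _lt50_probit_time(s)
    raise ValueError(f"unknown method {method!r}")


def _lt50_interpolate(s: np.ndarray) -> Optional[float]:
    idx = np.nonzero(s >= 0.5)[0]
    if idx.size == 0:
        return CENSORED
    d = int(idx[0]) + 1  # 1-based day
    s_d = s[d - 1]
    s_prev = s[d - 2] if d >= 2 else 0.0
    if s_d == s_prev:  # already at exactly 0.5 on the first day
        return float(d)
    t = (d - 1) + (0.5 - s_prev) / (s_d - s_prev)
    return float(max(t, 1.0))


def _lt50_probit_time(s: np.ndarray) -> Optional[float]:
    w = s.size
    days = np.arange(1, w + 1, dtype=float)
    inc = np.diff(np.concatenate([[0.0], s]))  # daily increments (proportions)
    surv = 1.0 - s[-1]
    logt = np.log10(days)

    def nll(theta: np.ndarray) -> float:
        a, b = theta
        cdf = stats.norm.cdf(a + b * logt)
        cell = np.diff(np.concatenate([[0.0], cdf]))
        cell = np.clip(cell, 1e-12, 1.0)
        tail = max(1.0 - cdf[-1], 1e-12)
        return -float(np.sum(inc * np.log(cell)) + surv * math.log(tail))

    if np.count_nonzero(inc) == 0:
        return CENSORED
    res = optimize.minimize(nll, np.array([0.0, 1.0]), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    a, b = res.x
    if not res.success or b <= 0:
        return CENSORED
    lt = 10.0 ** (-a / b)
    if lt > w or s[-1] < 0.5:
        return CENSORED
    return float(max(lt, 1.0))


def lt50_aggregate(per_replicate: Sequence[Optional[float]]) -> tuple[Optional[float], Optional[float], int]:
    """Mean and standard error of uncensored per-replicate LT50 values.

    Returns (mean, se, n_censored); mean/se are ``None`` when every
    replicate is censored. SE is sample SD / sqrt(r) (0 for r = 1).
    """
    vals = [v for v in per_replicate if v is not None]
    n_cens = len(per_replicate) - len(vals)
    if not vals:
        return None, None, n_cens
    mean = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
    return mean, se, n_cens


def estimate_lt50(
    assays: Sequence[MortalityAssay],
    method: str = "interpolation",
    abbott_daily: bool = False,
    control_series: Optional[Sequence[float]] = None,
) -> LTEstimate:
    """LT50 for one isolate x dose group of replicate assays.

    With ``abbott_daily`` the cumulative series is Abbott-corrected day by
    day against ``control_series`` before the crossing is located; by
    default uncorrected treatment mortality is used (control mortality in
    these assays is near zero).
    """
    if not assays:
        raise ValueError("no assays supplied")
    ids = {a.isolate_id for a in assays}
    doses = {a.dose for a in assays}
    if len(ids) > 1 or len(doses) > 1:
        raise ValueError("assays must share isolate and dose")
    per_rep: list[Optional[float]] = []
    for a in assays:
        s = cumulative_mortality_series(a)
        if abbott_daily:
            if control_series is None:
                raise ValueError("abbott_daily requires a control series")
            c = np.asarray(control_series, dtype=float)
            s = np.array([abbott(100 * t, 100 * cc, clamp=True) / 100.0 for t, cc in zip(s, c)])
            s = np.maximum.accumulate(s)
        per_rep.append(lt50_replicate(s, method=method))
    mean, se, n_cens = lt50_aggregate(per_rep)
    return LTEstimate(
        isolate_id=ids.pop(), dose=doses.pop(), per_replicate=per_rep,
        mean=mean, se=se, n_censored=n_cens, method=method,
    )
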