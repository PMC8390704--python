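"""Seeded synthetic bioassay generator with retained ground truth.

Emulates the study design the analysis modules expect: a decadal dose grid
of 1e4..1e8 spores/ml, 3 replicates of 20 larvae per dose, a 7-day
observation window for the leafminer dose-response assay and a 10-day
window for the wax-moth screening assay. Final deaths per replicate are
binomial with probability C + (1-C) * Phi(alpha + beta * log10 c); death
days follow a discretized log-normal whose median shifts downward with log
dose, so higher doses kill faster. The latent per-isolate parameters are
retained (SyntheticTruth) for parameter-recovery tests.

Each isolate draws from its own random substream keyed by (seed, isolate
index, stage), so adding isolates or stages never perturbs earlier draws.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .data_model import (
    GerminationAssay,
    Host,
    IsolateRecord,
    MortalityAssay,
    SoilSource,
    SporulationAssay,
)

_STAGE_DOSE = 0
_STAGE_SCREEN = 1

DEFAULT_DOSE_GRID = (1e4, 1e5, 1e6, 1e7, 1e8)


class TimeModel(BaseModel):
    """Dose-shifted log-normal time-to-death model.

    median log10-days are normal around log10 m(c) with scale ``sigma``,
    where m(c) = median_at_ref_dose - dose_sensitivity * (log10 c - log10
    ref_dose), clipped to at least 1 day. Defaults put LT50 between about 2
    and 4 days across the decadal grid, inside the 1.9-5.7-day span typical
    of virulent isolates.
    """

    median_at_ref_dose: float = Field(default=3.0, gt=0)
    ref_dose: float = Field(default=1e6, gt=0)
    dose_sensitivity: float = Field(default=0.5, ge=0)
    sigma: float = Field(default=0.15, gt=0)

    def median(self, dose: float) -> float:
        m = self.median_at_ref_dose - self.dose_sensitivity * (
            np.log10(dose) - np.log10(self.ref_dose)
        )
        return float(max(m, 1.0))


class SyntheticConfig(BaseModel):
    seed: int
    n_isolates: int = Field(default=27, ge=1)
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    replicates: int = Field(default=3, ge=1)
    larvae_per_replicate: int = Field(default=20, ge=1)
    window_days: int = Field(default=7, ge=1)
    screen_window_days: int = Field(default=10, ge=1)
    screen_dose: float = Field(default=1e7, gt=0)
    alpha_range: tuple[float, float] = (-2.8, -1.2)
    beta_range: tuple[float, float] = (0.35, 0.9)
    control_mortality_range: tuple[float, float] = (0.0, 0.05)
    germination_range: tuple[float, float] = (0.80, 0.97)
    dpcs_range: tuple[float, float] = (10.0, 16.0)
    sporulation_window_end: float = Field(default=20.0, gt=0)
    galleria_mortality_range: tuple[float, float] = (0.75, 1.0)
    time_model: TimeModel = Field(default_factory=TimeModel)
    include_controls: bool = True

    @model_validator(mode="after")
    def _ranges_ordered(self) -> "SyntheticConfig":
        for name in ("alpha_range", "beta_range", "control_mortality_range",
                     "germination_range", "dpcs_range", "galleria_mortality_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: {lo} > {hi}")
        if any(c <= 0 for c in self.dose_grid) or len(self.dose_grid) == 0:
            raise ValueError("dose_grid must be positive and non-empty")
        for name in ("control_mortality_range", "germination_range", "galleria_mortality_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo and hi <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        return self


class IsolateTruth(BaseModel):
    isolate_id: str
    alpha: float
    beta: float
    control_mortality: float
    lc50: float
    p_germination: float
    dpcs_day: float
    p_galleria_mortality: float


class SyntheticTruth(BaseModel):
    config: SyntheticConfig
    isolates: list[IsolateTruth]

    def lt50_true(self, dose: float) -> float:
        """Latent median time to death at ``dose`` under the time model."""
        return self.config.time_model.median(dose)


def _rng(config: SyntheticConfig, index: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, index, stage])


def _isolate_id(index: int) -> str:
    return f"SYN{index + 1:03d}"


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Draw per-isolate latent parameters uniformly from the configured ranges."""
    isolates = []
    for i in range(config.n_isolates):
        rng = _rng(config, i, stage=9)  # truth stream, separate from assay streams
        alpha = rng.uniform(*config.alpha_range)
        beta = rng.uniform(*config.beta_range)
        c = rng.uniform(*config.control_mortality_range)
        isolates.append(IsolateTruth(
            isolate_id=_isolate_id(i),
            alpha=alpha,
            beta=beta,
            control_mortality=c,
            lc50=float(10.0 ** (-alpha / beta)) if beta != 0 else float("nan"),
            p_germination=rng.uniform(*config.germination_range),
            dpcs_day=rng.uniform(*config.dpcs_range),
            p_galleria_mortality=rng.uniform(*config.galleria_mortality_range),
        ))
    return SyntheticTruth(config=config, isolates=isolates)


def _death_days(
    rng: np.random.Generator, n_dead: int, dose: float, window: int, tm: TimeModel
) -> np.ndarray:
    """Cumulative daily death counts for ``n_dead`` larvae dying in-window."""
    cum = np.zeros(window, dtype=int)
    if n_dead == 0:
        return cum
    t = 10.0 ** rng.normal(np.log10(tm.median(dose)), tm.sigma, size=n_dead)
    days = np.clip(np.ceil(t).astype(int), 1, window)
    for d in days:
        cum[d - 1:] += 1
    return cum


def _phi(z: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.cdf(z)


def simulate_dose_mortality(truth: SyntheticTruth, config: Optional[SyntheticConfig] = None) -> list[MortalityAssay]:
    """Dose-series (and control) mortality assays for every isolate."""
    cfg = config or truth.config
    out: list[MortalityAssay] = []
    for i, iso in enumerate(truth.isolates):
        rng = _rng(cfg, i, _STAGE_DOSE)
        for dose in cfg.dose_grid:
            p = iso.control_mortality + (1 - iso.control_mortality) * float(
                _phi(np.array([iso.alpha + iso.beta * np.log10(dose)]))[0]
            )
            for rep in range(1, cfg.replicates + 1):
                dead = int(rng.binomial(cfg.larvae_per_replicate, p))
                cum = _death_days(rng, dead, dose, cfg.window_days, cfg.time_model)
                out.append(MortalityAssay(
                    isolate_id=iso.isolate_id, host=Host.tuta, instar=3, dose=dose,
                    replicate=rep, n_exposed=cfg.larvae_per_replicate,
                    deaths_by_day=tuple(cum), window_days=cfg.window_days,
                ))
        if cfg.include_controls:
            for rep in range(1, cfg.replicates + 1):
                dead = int(rng.binomial(cfg.larvae_per_replicate, iso.control_mortality))
                days = rng.integers(1, cfg.window_days + 1, size=dead)
                cum = np.zeros(cfg.window_days, dtype=int)
                for d in days:
                    cum[d - 1:] += 1
                out.append(MortalityAssay(
                    isolate_id=iso.isolate_id, host=Host.tuta, instar=3, dose=0.0,
                    replicate=rep, n_exposed=cfg.larvae_per_replicate,
                    deaths_by_day=tuple(cum), window_days=cfg.window_days,
                ))
    return out


def simulate_screening_assays(
    truth: SyntheticTruth, config: Optional[SyntheticConfig] = None
) -> tuple[list[GerminationAssay], list[SporulationAssay], list[MortalityAssay]]:
    """Germination, plate-sporulation and wax-moth screening assays."""
    cfg = config or truth.config
    germ: list[GerminationAssay] = []
    spor: list[SporulationAssay] = []
    mort: list[MortalityAssay] = []
    for i, iso in enumerate(truth.isolates):
        rng = _rng(cfg, i, _STAGE_SCREEN)
        for rep in range(1, cfg.replicates + 1):
            germ.append(GerminationAssay(
                isolate_id=iso.isolate_id, replicate=rep,
                n_counted=100, n_germinated=int(rng.binomial(100, iso.p_germination)),
            ))
            day = float(np.clip(iso.dpcs_day + rng.normal(0.0, 0.8), 1.0,
                                cfg.sporulation_window_end))
            spor.append(SporulationAssay(
                isolate_id=iso.isolate_id, replicate=rep, dpcs_day=day,
                window_end_day=cfg.sporulation_window_end,
            ))
            dead = int(rng.binomial(cfg.larvae_per_replicate, iso.p_galleria_mortality))
            cum = _death_days(rng, dead, cfg.screen_dose, cfg.screen_window_days,
                              cfg.time_model)
            mort.append(MortalityAssay(
                isolate_id=iso.isolate_id, host=Host.galleria, instar=3, dose=None,
                replicate=rep, n_exposed=cfg.larvae_per_replicate,
                deaths_by_day=tuple(cum), window_days=cfg.screen_window_days,
            ))
    return germ, spor, mort


def isolate_records(truth: SyntheticTruth) -> list[IsolateRecord]:
    sources = [SoilSource.cropland, SoilSource.grassland, SoilSource.forest]
    return [
        IsolateRecord(isolate_id=iso.isolate_id, source=sources[i % 3],
                      species_label="Beauveria bassiana (synthetic)")
        for i, iso in enumerate(truth.isolates)
    ]


def generate_dataset(config: SyntheticConfig, out_dir: str | Path, force: bool = False) -> SyntheticTruth:
    """Write the full synthetic CSV bundle plus truth.csv and a manifest."""
    from . import io as _io

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    truth = generate_truth(config)
    germ, spor, screen_mort = simulate_screening_assays(truth)
    dose_mort = simulate_dose_mortality(truth)

    _io.write_isolates(isolate_records(truth), out / "isolates.csv")
    _io.write_germination(germ, out / "germination.csv")
    _io.write_sporulation(spor, out / "sporulation.csv")
    _io.write_mortality(screen_mort + dose_mort, out / "mortality.csv")
    _io.write_truth(truth, out / "truth.csv")
    manifest = {"config": json.loads(config.model_dump_json()), "seed": config.seed}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return truth
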