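"""End-to-end orchestration: simulate/load -> screen -> dose-response ->
time-response -> phenotype -> report.

Each stage consumes the previous stage's outputs, writes plain CSV, and is
deterministic given the run configuration, so re-running a stage on
unchanged inputs reproduces identical files. A JSON manifest records the
configuration, seed, stage list and SHA-256 digests of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import dose_response as dr
from . import phenotyping as ph
from . import screening as sc
from . import time_response as tr
from .data_model import Host
from .io import RunConfig, read_dataset
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("epfassay")

try:  # package version for the manifest
    from importlib.metadata import version as _pkg_version

    _VERSION = _pkg_version("epfassay")
except Exception:  # pragma: no cover - source tree without install
    _VERSION = "0.0.0+src"


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and offending input."""


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _group_by_isolate(records):
    groups = defaultdict(list)
    for r in records:
        groups[r.isolate_id].append(r)
    return groups


def screening_stage(data: dict, config: RunConfig) -> pd.DataFrame:
    germ = _group_by_isolate(data.get("germination", []))
    spor = _group_by_isolate(data.get("sporulation", []))
    mort = _group_by_isolate(
        [m for m in data.get("mortality", []) if m.host == Host.galleria and m.dose is None]
    )
    results = []
    for iso in sorted(germ):
        if iso not in spor or iso not in mort:
            raise StageError(f"screen: isolate {iso} lacks sporulation or mortality records")
        results.append(sc.score_isolate(
            iso, germ[iso], spor[iso], mort[iso],
            weights=config.bei_weights, window_end_day=config.sporulation_window_end,
        ))
    sc.screen(results, threshold=config.bei_threshold)
    rows = [{
        "isolate_id": r.isolate_id, "sg_pct": r.sg_pct, "rsr": r.rsr,
        "lm_pct": r.lm_pct, "bei_pct": r.bei_pct, "bei_group": r.bei_group,
        "efficacy": r.efficacy, "selected": int(r.selected),
    } for r in results]
    df = pd.DataFrame(rows).sort_values(
        "bei_pct", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    log.info("screen: %d isolates, %d selected (BEI > %s)",
             len(df), int(df["selected"].sum()), config.bei_threshold)
    return df


def dose_response_stage(data: dict, config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    series = [m for m in data.get("mortality", []) if m.dose is not None and m.dose > 0
              and m.host == Host.tuta]
    groups = _group_by_isolate(series)
    controls = _group_by_isolate([m for m in data.get("mortality", []) if m.dose == 0])
    fit_rows, lc_rows = [], []
    for iso in sorted(groups):
        table = dr.DoseMortalityTable.from_assays(groups[iso])
        ctrl_pct = dr.control_mortality_percent(controls.get(iso, []))
        try:
            fit = dr.fit_probit(table, control_mortality_pct=ctrl_pct,
                                natural_response=config.natural_response)
        except ValueError as exc:
            if "no gradient information" in str(exc):
                # uniform kill/survival at every dose: LC lies outside the
                # tested range; record the isolate and move on
                log.warning("doseresponse: isolate %s: %s", iso, exc)
                fit_rows.append({
                    "isolate_id": iso, "alpha": float("nan"), "beta": float("nan"),
                    "se_alpha": float("nan"), "se_beta": float("nan"),
                    "natural_mortality": ctrl_pct / 100.0, "chi2": float("nan"),
                    "df": 0, "heterogeneity": float("nan"), "converged": 0,
                    "separation": 0, "n_doses": len(table.doses),
                    "n_total": float(table.n.sum()), "method": "degenerate",
                })
                continue
            raise StageError(f"doseresponse: isolate {iso}: {exc}") from exc
        fit_rows.append({
            "isolate_id": iso, "alpha": fit.alpha, "beta": fit.beta,
            "se_alpha": fit.se_alpha, "se_beta": fit.se_beta,
            "natural_mortality": fit.natural_mortality, "chi2": fit.chi2,
            "df": fit.df, "heterogeneity": fit.heterogeneity,
            "converged": int(fit.converged), "separation": int(fit.separation),
            "n_doses": fit.n_doses, "n_total": fit.n_total, "method": fit.method,
        })
        for p in config.lc_levels:
            est = dr.fiducial_limits(fit, p, confidence=config.confidence)
            lc_rows.append({
                "isolate_id": iso, "p": p, "lc": est.lc, "lower": est.lower,
                "upper": est.upper, "g": est.g, "unbounded": int(est.unbounded),
            })
    return pd.DataFrame(fit_rows), pd.DataFrame(lc_rows)


def time_response_stage(data: dict, config: RunConfig) -> pd.DataFrame:
    series = [m for m in data.get("mortality", []) if m.dose is not None and m.dose > 0
              and m.host == Host.tuta]
    groups = defaultdict(list)
    for m in series:
        if any(abs(m.dose - d) / d < 1e-9 for d in config.lt_doses):
            groups[(m.isolate_id, m.dose)].append(m)
    rows = []
    for iso, dose in sorted(groups):
        est = tr.estimate_lt50(groups[(iso, dose)], method=config.lt_method)
        rows.append({
            "isolate_id": iso, "dose": dose, "method": est.method,
            "lt50_mean": est.mean, "lt50_se": est.se, "n_censored": est.n_censored,
        })
    return pd.DataFrame(rows)


def phenotype_stage(data: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    temp_rows, enz_rows = [], []
    for iso, assays in sorted(_group_by_isolate(data.get("temperature", [])).items()):
        prof = ph.temperature_profile(assays)
        for t in sorted(prof.germination_pct):
            temp_rows.append({
                "isolate_id": iso, "temperature": t,
                "germination_pct": prof.germination_pct[t],
                "radial_diameter_mm": prof.radial_diameter_mm[t],
                "radial_net_growth_mm": prof.radial_net_growth_mm[t],
                "sporulation_start_day": prof.sporulation_start_day[t],
                "optimum_temperature": prof.optimum_temperature,
            })
    for e in data.get("enzymes", []):
        enz_rows.append({"isolate_id": e.isolate_id, "enzyme": e.enzyme,
                         "grade": e.grade, "symbol": ph.enzyme_symbol(e.grade)})
    return pd.DataFrame(temp_rows), pd.DataFrame(enz_rows)


def render_report(tables: dict[str, pd.DataFrame], config: RunConfig) -> str:
    """Deterministic Markdown report over the result tables."""
    lines = ["# Bioassay analysis report", ""]
    scr = tables.get("screening_results")
    if scr is not None:
        n_sel = int(scr["selected"].sum())
        lines += [f"## Screening ({len(scr)} isolates)", ""]
        if n_sel:
            sel = ", ".join(scr.loc[scr["selected"] == 1, "isolate_id"])
            lines.append(
                f"{n_sel} isolate(s) passed the BEI > {config.bei_threshold:g} screen: {sel}."
            )
        else:
            lines.append("Zero isolates passed screening.")
        lines += ["", scr.to_csv(index=False).rstrip(), ""]
    if "probit_fits" in tables and not tables["probit_fits"].empty:
        lines += ["## Dose-response (probit fits)", "",
                  tables["probit_fits"].to_csv(index=False).rstrip(), "",
                  "## Lethal concentrations with fiducial limits", "",
                  tables["lc_estimates"].to_csv(index=False).rstrip(), ""]
    if "lt_estimates" in tables and not tables["lt_estimates"].empty:
        lines += ["## Median lethal times", "",
                  tables["lt_estimates"].to_csv(index=False).rstrip(), ""]
    for name, heading in (("temperature_profiles", "Temperature profiles"),
                          ("enzyme_grades", "Enzyme grades")):
        if name in tables and not tables[name].empty:
            lines += [f"## {heading}", "", tables[name].to_csv(index=False).rstrip(), ""]
    return "\n".join(lines) + "\n"


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    input_dir: Optional[str | Path] = None,
    simulate: Optional[SyntheticConfig] = None,
) -> Path:
    """Run every applicable stage and write results + report + manifest.

    Exactly one of ``input_dir`` (a CSV bundle) or ``simulate`` (a synthetic
    data configuration) must be given.
    """
    if (input_dir is None) == (simulate is None):
        raise ValueError("provide exactly one of input_dir or simulate")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    if simulate is not None:
        input_dir = out / "inputs"
        generate_dataset(simulate, input_dir, force=True)
        stages.append("simulate")
    data = read_dataset(input_dir)
    if "mortality" not in data:
        raise FileNotFoundError(f"required input missing: {Path(input_dir) / 'mortality.csv'}")
    stages.append("load")

    tables: dict[str, pd.DataFrame] = {}
    if "germination" in data and "sporulation" in data:
        tables["screening_results"] = screening_stage(data, config)
        stages.append("screen")
    has_series = any(m.dose is not None and m.dose > 0 for m in data.get("mortality", []))
    if has_series:
        tables["probit_fits"], tables["lc_estimates"] = dose_response_stage(data, config)
        stages.append("doseresponse")
        tables["lt_estimates"] = time_response_stage(data, config)
        stages.append("timeresponse")
    if "temperature" in data or "enzymes" in data:
        tables["temperature_profiles"], tables["enzyme_grades"] = phenotype_stage(data)
        stages.append("phenotype")

    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "report.md").write_text(render_report(tables, config))
    stages.append("report")

    manifest = {
        "config": json.loads(config.model_dump_json()),
        "seed": config.seed,
        "stages": stages,
        "outputs": {f"{n}.csv": _digest(out / f"{n}.csv") for n in tables}
        | {"report.md": _digest(out / "report.md")},
        "version": _VERSION,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
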