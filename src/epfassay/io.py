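"""Delimited-text readers and writers for every assay table.

All tables are comma-separated UTF-8 with one header row and "." decimals.
Cumulative daily deaths are serialized as a semicolon-joined column
(``deaths_by_day = "0;2;5;..."``) so one row carries one replicate
regardless of window length. Readers validate every record against its
type invariants and report the offending file and line on failure.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from .data_model import (
    EnzymeAssay,
    GerminationAssay,
    IsolateRecord,
    MortalityAssay,
    SporulationAssay,
    TemperatureAssay,
)


class DatasetValidationError(ValueError):
    """A record violated its schema; message names file, line and invariant."""


class RunConfig(BaseModel):
    """Plain-text run configuration shared by the CLI stages."""

    seed: int = 0
    bei_weights: tuple[float, float, float] = (37.0, 13.0, 50.0)
    bei_threshold: float = 80.0
    sporulation_window_end: float = 20.0
    screen_window_days: int = Field(default=10, ge=1)
    dose_window_days: int = Field(default=7, ge=1)
    confidence: float = 0.95
    lc_levels: tuple[float, ...] = (0.5, 0.9)
    lt_doses: tuple[float, ...] = (1e4, 1e6, 1e8)
    lt_method: str = "interpolation"
    natural_response: str = "abbott"


def read_run_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"{path}: missing columns {missing}")
    return df


def _build(model, row: dict, path: Path, line: int):
    try:
        return model(**row)
    except (ValidationError, ValueError) as exc:
        raise DatasetValidationError(f"{path}, line {line}: {exc}") from exc


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def read_isolates(path: str | Path) -> list[IsolateRecord]:
    path = Path(path)
    df = _read_table(path, ["isolate_id", "source"])
    dupes = df["isolate_id"][df["isolate_id"].duplicated()].tolist()
    if dupes:
        raise DatasetValidationError(f"{path}: duplicate isolate_id {sorted(set(dupes))}")
    out = []
    for idx, row in df.iterrows():
        rec = {
            "isolate_id": row["isolate_id"],
            "source": row["source"],
            "species_label": row.get("species_label", "") if isinstance(row.get("species_label"), str) else "",
            "accession": row.get("accession") if isinstance(row.get("accession"), str) else None,
        }
        out.append(_build(IsolateRecord, rec, path, idx + 2))
    return out


def read_germination(path: str | Path) -> list[GerminationAssay]:
    path = Path(path)
    df = _read_table(path, ["isolate_id", "replicate", "n_counted", "n_germinated"])
    return [
        _build(GerminationAssay, {
            "isolate_id": row["isolate_id"], "replicate": int(row["replicate"]),
            "temperature": float(row.get("temperature", 25.0) or 25.0),
            "n_counted": int(row["n_counted"]), "n_germinated": int(row["n_germinated"]),
        }, path, idx + 2)
        for idx, row in df.iterrows()
    ]


def read_sporulation(path: str | Path) -> list[SporulationAssay]:
    path = Path(path)
    df = _read_table(path, ["isolate_id", "replicate", "dpcs_day", "window_end_day"])
    return [
        _build(SporulationAssay, {
            "isolate_id": row["isolate_id"], "replicate": int(row["replicate"]),
            "dpcs_day": _opt_float(row["dpcs_day"]),
            "window_end_day": float(row["window_end_day"]),
        }, path, idx + 2)
        for idx, row in df.iterrows()
    ]


def read_mortality(path: str | Path) -> list[MortalityAssay]:
    path = Path(path)
    df = _read_table(path, ["isolate_id", "host", "dose", "replicate", "n_exposed",
                            "window_days", "deaths_by_day"])
    out = []
    for idx, row in df.iterrows():
        try:
            series = tuple(int(x) for x in str(row["deaths_by_day"]).split(";"))
        except ValueError as exc:
            raise DatasetValidationError(
                f"{path}, line {idx + 2}: unparseable deaths_by_day {row['deaths_by_day']!r}"
            ) from exc
        out.append(_build(MortalityAssay, {
            "isolate_id": row["isolate_id"], "host": row["host"],
            "instar": int(row.get("instar", 3) or 3),
            "dose": _opt_float(row["dose"]), "replicate": int(row["replicate"]),
            "n_exposed": int(row["n_exposed"]), "deaths_by_day": series,
            "window_days": int(row["window_days"]),
        }, path, idx + 2))
    return out


def read_temperature(path: str | Path) -> list[TemperatureAssay]:
    path = Path(path)
    df = _read_table(path, ["isolate_id", "temperature", "germination_pct"])
    return [
        _build(TemperatureAssay, {
            "isolate_id": row["isolate_id"], "temperature": float(row["temperature"]),
            "germination_pct": float(row["germination_pct"]),
            "radial_diameter_mm": float(row.get("radial_diameter_mm", 0.0) or 0.0),
            "sporulation_start_day": _opt_float(row.get("sporulation_start_day")),
        }, path, idx + 2)
        for idx, row in df.iterrows()
    ]


def read_enzymes(path: str | Path) -> list[EnzymeAssay]:
    path = Path(path)
    df = _read_table(path, ["isolate_id", "enzyme", "grade"])
    return [
        _build(EnzymeAssay, {
            "isolate_id": row["isolate_id"], "enzyme": row["enzyme"],
            "grade": int(row["grade"]),
        }, path, idx + 2)
        for idx, row in df.iterrows()
    ]


# --- writers -------------------------------------------------------------

def _write(df: pd.DataFrame, path: str | Path, columns: Sequence[str]) -> None:
    # an empty table still gets its header row, so write/read round-trips
    if df.empty:
        df = pd.DataFrame(columns=list(columns))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def write_isolates(records: Sequence[IsolateRecord], path: str | Path) -> None:
    _write(pd.DataFrame([{
        "isolate_id": r.isolate_id, "source": r.source.value,
        "species_label": r.species_label, "accession": r.accession,
    } for r in records]), path, ["isolate_id", "source", "species_label", "accession"])


def write_germination(records: Sequence[GerminationAssay], path: str | Path) -> None:
    _write(pd.DataFrame([{
        "isolate_id": r.isolate_id, "replicate": r.replicate, "temperature": r.temperature,
        "n_counted": r.n_counted, "n_germinated": r.n_germinated,
    } for r in records]), path, ["isolate_id", "replicate", "temperature", "n_counted", "n_germinated"])


def write_sporulation(records: Sequence[SporulationAssay], path: str | Path) -> None:
    _write(pd.DataFrame([{
        "isolate_id": r.isolate_id, "replicate": r.replicate, "temperature": r.temperature,
        "dpcs_day": r.dpcs_day, "window_end_day": r.window_end_day,
    } for r in records]), path, ["isolate_id", "replicate", "temperature", "dpcs_day", "window_end_day"])


def write_mortality(records: Sequence[MortalityAssay], path: str | Path) -> None:
    _write(pd.DataFrame([{
        "isolate_id": r.isolate_id, "host": r.host.value, "instar": r.instar,
        "dose": r.dose, "replicate": r.replicate, "n_exposed": r.n_exposed,
        "window_days": r.window_days,
        "deaths_by_day": ";".join(str(d) for d in r.deaths_by_day),
    } for r in records]), path, ["isolate_id", "host", "instar", "dose", "replicate", "n_exposed", "window_days", "deaths_by_day"])


def write_temperature(records: Sequence[TemperatureAssay], path: str | Path) -> None:
    _write(pd.DataFrame([{
        "isolate_id": r.isolate_id, "temperature": r.temperature,
        "germination_pct": r.germination_pct,
        "radial_diameter_mm": r.radial_diameter_mm,
        "sporulation_start_day": r.sporulation_start_day,
    } for r in records]), path, ["isolate_id", "temperature", "germination_pct", "radial_diameter_mm", "sporulation_start_day"])


def write_enzymes(records: Sequence[EnzymeAssay], path: str | Path) -> None:
    _write(pd.DataFrame([{
        "isolate_id": r.isolate_id, "enzyme": r.enzyme, "grade": r.grade,
    } for r in records]), path, ["isolate_id", "enzyme", "grade"])


def write_truth(truth, path: str | Path) -> None:
    _write(pd.DataFrame([t.model_dump() for t in truth.isolates]), path,
           ["isolate_id", "alpha", "beta", "control_mortality", "lc50",
            "p_germination", "dpcs_day", "p_galleria_mortality"])


def read_dataset(directory: str | Path) -> dict:
    """Read every table present in ``directory`` into validated records.

    Returns a dict with keys isolates, germination, sporulation, mortality,
    temperature, enzymes (absent files are simply missing keys).
    """
    directory = Path(directory)
    readers = {
        "isolates": read_isolates, "germination": read_germination,
        "sporulation": read_sporulation, "mortality": read_mortality,
        "temperature": read_temperature, "enzymes": read_enzymes,
    }
    out = {}
    for name, reader in readers.items():
        p = directory / f"{name}.csv"
        if p.exists():
            out[name] = reader(p)
    if not out:
        raise FileNotFoundError(f"no recognized tables in {directory}")
    return out
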