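"""CSV dialects, configuration files and result reports.

On-disk units are the user-facing ones (kPa, mm, g, s); conversion to SI
happens here, at the boundary, and nowhere else.

Dialects::

    flow CSV   : pressure_kPa, replicate, mass_g, duration_s
    trace CSV  : pressure_kPa, time_s, length_mm      (one block per pressure)

Writers emit 9 significant digits, enough for a lossless round-trip at the
measurement scales involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import units
from .core import NozzleGeometry, PowerLawRheology, SwellLaw
from .errors import ParseError
from .fitting import FlowRateDataset
from .traces import FilamentTrace, mass_to_flow, segment_trace

__all__ = [
    "FLOW_COLUMNS",
    "TRACE_COLUMNS",
    "read_flow_csv",
    "write_flow_csv",
    "flow_dataset_from_masses",
    "read_trace_csv",
    "write_trace_csv",
    "write_results",
    "RunConfig",
    "load_config",
]

FLOW_COLUMNS = ("pressure_kPa", "replicate", "mass_g", "duration_s")
TRACE_COLUMNS = ("pressure_kPa", "time_s", "length_mm")
_FLOAT_FMT = "%.9g"


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    for col in required:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()].tolist()
        if bad:
            raise ParseError(f"{path}: non-numeric value(s) in column {col!r}, row(s) {bad}")
        df[col] = values
    return df


def read_flow_csv(path: str | Path) -> pd.DataFrame:
    """Read a flow-assay CSV (masses per pressure and replicate)."""
    return _read_csv(path, FLOW_COLUMNS)


def write_flow_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def flow_dataset_from_masses(
    df: pd.DataFrame, nozzle: NozzleGeometry, density: float
) -> FlowRateDataset:
    """Convert a masses table to per-pressure replicate flow rates (SI)."""
    records = []
    for p_kpa, group in df.groupby("pressure_kPa", sort=True):
        flows = [
            units.g_to_kg(m) / (density * t)
            for m, t in zip(group["mass_g"], group["duration_s"])
        ]
        records.append((units.kpa_to_pa(float(p_kpa)), flows))
    return FlowRateDataset(records=records, nozzle=nozzle)


def read_trace_csv(path: str | Path, time_tolerance: float = 1e-6) -> list[FilamentTrace]:
    """Read filament traces, one per pressure block, and segment them.

    Sampling must be uniform within ``time_tolerance`` seconds.
    """
    df = _read_csv(path, TRACE_COLUMNS)
    traces = []
    for p_kpa, group in df.groupby("pressure_kPa", sort=True):
        times = group["time_s"].to_numpy(dtype=float)
        dt = np.diff(times)
        if len(dt) and np.any(np.abs(dt - dt[0]) > time_tolerance):
            bad_rows = group.index[1:][np.abs(dt - dt[0]) > time_tolerance].tolist()
            raise ParseError(
                f"{path}: non-uniform time spacing at pressure {p_kpa} kPa, row(s) {bad_rows}"
            )
        trace = FilamentTrace(
            pressure=units.kpa_to_pa(float(p_kpa)),
            times=times,
            lengths=np.array([units.mm_to_m(x) for x in group["length_mm"]]),
        )
        traces.append(segment_trace(trace))
    return traces


def write_trace_csv(traces: Sequence[FilamentTrace], path: str | Path) -> None:
    frames = []
    for trace in traces:
        frames.append(
            pd.DataFrame(
                {
                    "pressure_kPa": units.pa_to_kpa(trace.pressure),
                    "time_s": trace.times,
                    "length_mm": [units.m_to_mm(x) for x in trace.lengths],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_results(payload: dict, path: str | Path) -> None:
    """Write a JSON report (numpy scalars coerced to plain floats/ints)."""

    def default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")


@dataclass(frozen=True)
class RunConfig:
    """User-level run configuration (YAML/JSON), user-facing units on disk.

    Defaults are the 22G half-inch nozzle and the bench protocol.
    """

    nozzle: NozzleGeometry = field(default_factory=NozzleGeometry.gauge_22)
    rheology: PowerLawRheology | None = None
    swell_law: SwellLaw | None = None
    density: float = 1000.0  # kg/m^3
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs: dict = {}
        if "nozzle" in raw:
            kwargs["nozzle"] = NozzleGeometry(
                inner_radius=units.mm_to_m(raw["nozzle"]["inner_radius_mm"]),
                length=units.mm_to_m(raw["nozzle"]["length_mm"]),
            )
        if "rheology" in raw:
            kwargs["rheology"] = PowerLawRheology(
                consistency_index=raw["rheology"]["K"],
                power_law_index=raw["rheology"]["n"],
            )
        if "swell_law" in raw:
            kwargs["swell_law"] = SwellLaw(
                offset=raw["swell_law"]["c1"],
                amplitude=raw["swell_law"]["c2"],
                exponent=raw["swell_law"]["beta"],
            )
        if "density_kg_m3" in raw:
            kwargs["density"] = float(raw["density_kg_m3"])
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON — YAML is a superset) run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.from_dict(raw)
    except KeyError as exc:
        raise ParseError(f"{path}: missing config key {exc}") from exc
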