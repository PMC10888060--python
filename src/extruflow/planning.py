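"""Prediction chain: extrusion speed at untested pressures and print planning.

Once (K, n) and (c1, c2, beta) are known, no further measurement is needed:
for any pressure the flow rate, wall shear stress, swell ratio, extrudate
radius and hence the natural extrusion speed follow in closed form, and the
printing speed required to deposit a strand of any target radius is
v_p = Q / (pi R_p^2).  ``speed_map`` tabulates both over a pressure grid for
a family of target radius ratios R_p/R — the planning chart a user consults
to pick printer settings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import units
from .core import (
    NozzleGeometry,
    PowerLawRheology,
    PrintPlan,
    Regime,
    SwellLaw,
    flow_rate,
    poi,
    printing_speed_for_radius,
    swell_ratio,
    wall_shear_stress,
)
from .errors import InvalidInputError

__all__ = ["SpeedMap", "predict_extrusion_speed", "plan_print", "speed_map"]

_MATCHED_RTOL = 1e-9


def predict_extrusion_speed(
    rheology: PowerLawRheology,
    swell_law: SwellLaw,
    nozzle: NozzleGeometry,
    pressure: float,
) -> float:
    """Extrusion speed (m/s) of the free strand at a given pressure.

    Chains the closed forms: Q(dP), tau_w(dP), R_ex = B(tau_w) * R, then
    volume conservation v_ex = Q / (pi R_ex^2).
    """
    q = flow_rate(rheology, nozzle, pressure)
    tau = wall_shear_stress(nozzle, pressure)
    rex = swell_ratio(swell_law, tau) * nozzle.inner_radius
    return q / (np.pi * rex**2)


def plan_print(
    rheology: PowerLawRheology,
    swell_law: SwellLaw,
    nozzle: NozzleGeometry,
    pressure: float,
    target_radius: float,
) -> PrintPlan:
    """Printing speed and POI for a target deposited-strand radius.

    The regime flag records whether the plan stretches the strand
    (v_p > v_ex), matches the extrusion speed, or compresses the deposit.
    """
    if target_radius <= 0:
        raise InvalidInputError(f"target_radius must be > 0, got {target_radius!r}")
    q = flow_rate(rheology, nozzle, pressure)
    tau = wall_shear_stress(nozzle, pressure)
    vp = printing_speed_for_radius(q, target_radius)
    vex = predict_extrusion_speed(rheology, swell_law, nozzle, pressure)
    if abs(vp - vex) <= _MATCHED_RTOL * vex:
        regime = Regime.MATCHED
    elif vp > vex:
        regime = Regime.STRETCHED
    else:
        regime = Regime.COMPRESSED
    return PrintPlan(
        pressure=pressure,
        printed_radius=target_radius,
        printing_speed=vp,
        poi=poi(target_radius, tau),
        regime_flag=regime,
    )


@dataclass(frozen=True)
class SpeedMap:
    """Tabulated planning chart over a pressure grid.

    ``extrusion_speeds[i]`` is v_ex at ``pressures[i]``; ``printing_speeds``
    has one row per entry of ``radius_ratios`` (R_p/R, equivalently the
    strand-diameter to nozzle-diameter ratio) giving the required v_p at each
    pressure.  All SI.
    """

    pressures: np.ndarray
    extrusion_speeds: np.ndarray
    radius_ratios: np.ndarray
    printing_speeds: np.ndarray  # shape (len(radius_ratios), len(pressures))
    nozzle: NozzleGeometry

    def to_dataframe(self) -> pd.DataFrame:
        """User-facing units: kPa and mm/s, one column per radius ratio."""
        data = {
            "pressure_kPa": [units.pa_to_kpa(p) for p in self.pressures],
            "vex_mm_s": [units.m_to_mm(v) for v in self.extrusion_speeds],
        }
        for ratio, row in zip(self.radius_ratios, self.printing_speeds):
            data[f"vp_mm_s_ratio_{ratio:g}"] = [units.m_to_mm(v) for v in row]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.9g")

    def to_json(self, path: str | Path) -> None:
        df = self.to_dataframe()
        payload = {
            "nozzle": {
                "inner_radius_mm": units.m_to_mm(self.nozzle.inner_radius),
                "length_mm": units.m_to_mm(self.nozzle.length),
            },
            "columns": list(df.columns),
            "rows": df.to_numpy().tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def speed_map(
    rheology: PowerLawRheology,
    swell_law: SwellLaw,
    nozzle: NozzleGeometry,
    pressure_grid: Sequence[float],
    radius_ratios: Sequence[float],
) -> SpeedMap:
    """Tabulate v_ex and the required v_p over pressures x radius ratios."""
    pressures = np.asarray(pressure_grid, dtype=float)
    ratios = np.asarray(radius_ratios, dtype=float)
    if pressures.size == 0 or ratios.size == 0:
        raise InvalidInputError("pressure_grid and radius_ratios must be non-empty")
    if np.any(ratios <= 0):
        raise InvalidInputError("radius ratios must be > 0")
    vex = np.array(
        [predict_extrusion_speed(rheology, swell_law, nozzle, p) for p in pressures]
    )
    vp = np.empty((ratios.size, pressures.size))
    for i, ratio in enumerate(ratios):
        target = ratio * nozzle.inner_radius
        for j, p in enumerate(pressures):
            vp[i, j] = plan_print(rheology, swell_law, nozzle, p, target).printing_speed
    return SpeedMap(
        pressures=pressures,
        extrusion_speeds=vex,
        radius_ratios=ratios,
        printing_speeds=vp,
        nozzle=nozzle,
    )
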