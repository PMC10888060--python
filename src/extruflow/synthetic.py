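"""Synthetic measurement generator for the whole extrusion pipeline.

Emulates the bench protocol end to end so every analysis stage can be
exercised, and its estimators validated by parameter recovery, without any
recorded data:

* **Flow assay** — per pressure and replicate, the mass collected over a
  fixed extrusion window, ``m = rho * Q_model(dP) * t * (1 + eps)`` with
  multiplicative Gaussian noise (balance + dispensing variability).
* **Hanging-filament traces** — length sampled every 250 ms.  Below a
  gravity-onset length the filament advances at the model extrusion speed;
  beyond it a *phenomenological* stretch term accelerates the tip,
  ``dl/dt = v_ex * (1 + g * max(0, l - l_onset))``, until the filament
  ruptures (at a length drawn uniformly from 30-35 mm) and a new one starts.
  The stretch term is a declared stand-in: real gravity-driven thinning is
  not modelled here, it exists so the short-filament speed filter has a
  regime to exclude.  Additive Gaussian noise on reported lengths stands in
  for pixel quantization (default 1 px at 0.05 mm/px).
* **Frames** — each trace sample rendered as a bright vertical bar below the
  nozzle tip on a noisy dark background.

Defaults mirror the study conditions: 70-130 kPa in 10 kPa steps, 5
replicates of 60 s extrusions, 0.25 s frame spacing, 22G half-inch nozzle,
and the fitted constants K = 222 Pa s^n, n = 0.23, c1 = 1.57,
c2 = 1.38e-10 Pa^-beta, beta = 3.15.  All randomness flows from one integer
seed; each stream (flow, each trace, frames) derives its own substream, so
outputs are bit-for-bit reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import units
from .core import NozzleGeometry, PowerLawRheology, SwellLaw, flow_rate
from .errors import InvalidInputError, RenderError
from .imaging import FrameImage
from .planning import predict_extrusion_speed
from .traces import FilamentTrace, segment_trace

__all__ = [
    "GeneratorConfig",
    "FrameRenderConfig",
    "synth_flow_dataset",
    "synth_trace",
    "synth_frames",
]

PAPER_RHEOLOGY = PowerLawRheology(consistency_index=222.0, power_law_index=0.23)
PAPER_SWELL_LAW = SwellLaw(offset=1.57, amplitude=1.38e-10, exponent=3.15)
DEFAULT_PRESSURES = tuple(units.kpa_to_pa(p) for p in range(70, 131, 10))
DEFAULT_PIXEL_SIZE = 0.05e-3  # m/px; 12.7 mm needle spanning 254 px


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the generator; defaults are the bench protocol."""

    rheology: PowerLawRheology = PAPER_RHEOLOGY
    swell_law: SwellLaw = PAPER_SWELL_LAW
    nozzle: NozzleGeometry = field(default_factory=NozzleGeometry.gauge_22)
    pressures: tuple[float, ...] = DEFAULT_PRESSURES  # Pa
    replicates: int = 5
    duration: float = 60.0  # s per flow replicate
    density: float = 1000.0  # kg/m^3; assumed hydrogel density for mass<->volume
    flow_noise_cv: float = 0.05  # multiplicative CV on collected masses
    trace_noise_sd: float = DEFAULT_PIXEL_SIZE  # additive SD on lengths (~1 px)
    frame_interval: float = 0.25  # s
    rupture_length_range: tuple[float, float] = (30e-3, 35e-3)  # m
    gravity_onset: float = 10e-3  # m; stretch begins beyond this length
    gravity_coeff: float = 50.0  # 1/m; tip speed ~doubles by ~30 mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.duration <= 0 or self.density <= 0:
            raise InvalidInputError("replicates >= 1, duration > 0, density > 0 required")
        if self.flow_noise_cv < 0 or self.trace_noise_sd < 0:
            raise InvalidInputError("noise parameters must be >= 0")
        low, high = self.rupture_length_range
        if not (0 < low < high):
            raise InvalidInputError("rupture_length_range must satisfy 0 < low < high")
        if any(p <= 0 for p in self.pressures):
            raise InvalidInputError("pressures must be > 0")
        if self.gravity_onset <= 0 or self.gravity_coeff < 0 or self.frame_interval <= 0:
            raise InvalidInputError("gravity_onset, frame_interval > 0; gravity_coeff >= 0")

    def manifest(self) -> dict:
        """JSON-serializable record of the exact generating conditions."""
        d = asdict(self)
        d["rheology"] = asdict(self.rheology)
        d["swell_law"] = asdict(self.swell_law)
        d["nozzle"] = asdict(self.nozzle)
        d["pressures"] = list(self.pressures)
        d["rupture_length_range"] = list(self.rupture_length_range)
        return d


def _rng(config: GeneratorConfig, *stream: int) -> np.random.Generator:
    # substream keyed on (seed, stream ids): independent, reproducible
    return np.random.default_rng([int(config.seed), *stream])


def synth_flow_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Simulated flow assay: one row per (pressure, replicate) with the mass.

    Columns (user-facing units, the on-disk dialect): pressure_kPa,
    replicate, mass_g, duration_s.  Noiseless (cv = 0) masses are exactly
    rho * Q_model * t.
    """
    rng = _rng(config, 1)
    rows = []
    for p in config.pressures:
        q = flow_rate(config.rheology, config.nozzle, p)
        for rep in range(1, config.replicates + 1):
            eps = rng.normal(0.0, config.flow_noise_cv) if config.flow_noise_cv > 0 else 0.0
            mass = config.density * q * config.duration * (1.0 + eps)
            rows.append(
                {
                    "pressure_kPa": units.pa_to_kpa(p),
                    "replicate": rep,
                    "mass_g": units.kg_to_g(mass),
                    "duration_s": config.duration,
                }
            )
    return pd.DataFrame(rows)


def synth_trace(
    config: GeneratorConfig,
    pressure: float,
    n_ruptures: int = 2,
    tail_samples: int = 20,
) -> FilamentTrace:
    """Simulate one hanging-filament length trace at the given pressure.

    Forward-Euler integration of the stretch ODE at the frame interval; the
    trace runs through ``n_ruptures`` ruptures plus a short tail of the next
    filament.  Reported lengths carry the additive measurement noise (clipped
    at 0) and the returned trace is already segmented.
    """
    if pressure <= 0:
        raise InvalidInputError(f"pressure must be > 0, got {pressure!r}")
    vex = predict_extrusion_speed(config.rheology, config.swell_law, config.nozzle, pressure)
    rng = _rng(config, 2, int(round(pressure)))
    low, high = config.rupture_length_range
    dt = config.frame_interval

    true_lengths = [0.0]
    ruptures_seen = 0
    tail_left = tail_samples
    rupture_at = rng.uniform(low, high)
    ell = 0.0
    while True:
        stretch = 1.0 + config.gravity_coeff * max(0.0, ell - config.gravity_onset)
        ell = ell + vex * stretch * dt
        if ell >= rupture_at:
            ell = 0.0
            ruptures_seen += 1
            rupture_at = rng.uniform(low, high)
        true_lengths.append(ell)
        if ruptures_seen >= n_ruptures:
            tail_left -= 1
            if tail_left <= 0:
                break

    arr = np.array(true_lengths)
    if config.trace_noise_sd > 0:
        arr = np.clip(arr + rng.normal(0.0, config.trace_noise_sd, size=arr.shape), 0.0, None)
    times = np.arange(len(arr)) * dt
    return segment_trace(FilamentTrace(pressure=pressure, times=times, lengths=arr))


@dataclass(frozen=True)
class FrameRenderConfig:
    """Geometry and noise of the synthetic frame renderer."""

    height_px: int = 800
    width_px: int = 64
    pixel_size: float = DEFAULT_PIXEL_SIZE  # m/px
    tip_row: int = 10
    filament_width_px: int = 8
    background_noise_sd: float = 0.02
    background_level: float = 0.1
    filament_level: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 2 or self.width_px < 1 or self.filament_width_px < 1:
            raise InvalidInputError("frame dimensions must be positive")
        if not (0 <= self.tip_row < self.height_px):
            raise InvalidInputError("tip_row outside the frame")
        if self.pixel_size <= 0 or self.background_noise_sd < 0:
            raise InvalidInputError("pixel_size > 0 and noise sd >= 0 required")


def synth_frames(trace: FilamentTrace, render: FrameRenderConfig) -> list[FrameImage]:
    """Render each trace sample as a frame: bright bar hanging below the tip.

    The bar spans round(l / pixel_size) rows starting just below the tip row,
    centred horizontally; Gaussian background noise is added and intensities
    clipped to [0, 1].  Deterministic for a given render seed.
    """
    rng = np.random.default_rng([int(render.seed), 3])
    max_rows = render.height_px - render.tip_row - 1
    frames = []
    col0 = (render.width_px - render.filament_width_px) // 2
    col1 = col0 + render.filament_width_px
    for ell in trace.lengths:
        n_rows = int(round(ell / render.pixel_size))
        if n_rows > max_rows:
            raise RenderError(
                f"filament of {ell:.4g} m ({n_rows} px) does not fit below tip row "
                f"{render.tip_row} in a {render.height_px}-px-high frame"
            )
        img = np.full((render.height_px, render.width_px), render.background_level)
        if n_rows > 0:
            img[render.tip_row + 1 : render.tip_row + 1 + n_rows, col0:col1] = (
                render.filament_level
            )
        if render.background_noise_sd > 0:
            img = img + rng.normal(0.0, render.background_noise_sd, size=img.shape)
        frames.append(
            FrameImage(
                pixels=np.clip(img, 0.0, 1.0),
                tip_row=render.tip_row,
                pixel_size=render.pixel_size,
            )
        )
    return frames
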