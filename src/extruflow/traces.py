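"""From raw measurements to flow rates, extrusion speeds and swell observations.

The measurement protocol this module digests: hydrogel is extruded for a
fixed duration into a dish and weighed (five replicates per pressure), giving
the volumetric flow rate; separately, a stationary print head extrudes a
free-hanging filament that is filmed, and the filament length is read off
frames taken every 250 ms.  The hanging filament accelerates once it is long
enough to stretch under its own weight and eventually ruptures (at roughly
30-35 mm), so the speed analysis keeps only early, short-filament points:
lengths up to 10 mm, and only the filaments formed before the second rupture.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .core import (
    NozzleGeometry,
    SwellObservation,
    extrudate_radius,
    wall_shear_stress,
)
from .errors import InsufficientDataError, InvalidInputError, MismatchError

__all__ = [
    "FilamentTrace",
    "SpeedEstimate",
    "mass_to_flow",
    "segment_trace",
    "extrusion_speed",
    "swell_observations",
    "DEFAULT_MAX_LENGTH",
    "DEFAULT_MAX_SEGMENTS",
    "RUPTURE_DROP_FRACTION",
]

DEFAULT_MAX_LENGTH = 10e-3  # m; beyond this, gravity-driven stretch contaminates the speed
DEFAULT_MAX_SEGMENTS = 2  # analyse filaments only up to the second rupture
RUPTURE_DROP_FRACTION = 0.5  # a >50% length drop between frames marks a rupture


@dataclass(frozen=True)
class FilamentTrace:
    """Length-versus-time samples of the hanging filament at one pressure.

    times are uniformly spaced (default 0.25 s); lengths in meters.
    segment_boundaries holds the sample indices at which a new filament
    starts after a rupture (index 0 is implicit); None means not yet
    segmented.
    """

    pressure: float
    times: np.ndarray
    lengths: np.ndarray
    segment_boundaries: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        lengths = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "lengths", lengths)
        if self.pressure <= 0:
            raise InvalidInputError(f"pressure must be > 0, got {self.pressure!r}")
        if times.shape != lengths.shape or times.ndim != 1:
            raise InvalidInputError("times and lengths must be 1-D arrays of equal length")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if np.any(lengths < 0):
            raise InvalidInputError("lengths must be >= 0")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def segment_slices(self) -> list[slice]:
        """Contiguous index ranges of the individual filaments (after segmentation)."""
        bounds = self.segment_boundaries if self.segment_boundaries is not None else ()
        starts = [0, *bounds]
        stops = [*bounds, len(self.times)]
        return [slice(a, b) for a, b in zip(starts, stops) if b > a]


@dataclass(frozen=True)
class SpeedEstimate:
    """Mean and SD of the filament's speed of descent at one pressure (m/s)."""

    pressure: float
    extrusion_speed_mean: float
    extrusion_speed_sd: float
    points_used: int

    def __post_init__(self) -> None:
        if self.extrusion_speed_mean <= 0:
            raise InvalidInputError(
                f"extrusion_speed_mean must be > 0, got {self.extrusion_speed_mean!r}"
            )
        if self.extrusion_speed_sd < 0 or self.points_used < 1:
            raise InvalidInputError("sd must be >= 0 and points_used >= 1")


def mass_to_flow(
    masses: Sequence[float], duration: float, density: float
) -> tuple[float, float]:
    """Convert replicate extruded masses (kg) to a volumetric flow rate (m^3/s).

    Each replicate gives Q = m / (rho * t); returns (mean, sample SD) over
    replicates (SD is 0 for a single replicate).
    """
    if len(masses) == 0:
        raise InsufficientDataError("no mass replicates given")
    if duration <= 0 or density <= 0:
        raise InvalidInputError("duration and density must be > 0")
    m = np.asarray(masses, dtype=float)
    if np.any(m <= 0):
        raise InvalidInputError("masses must be > 0")
    q = m / (density * duration)
    sd = float(np.std(q, ddof=1)) if len(q) > 1 else 0.0
    return float(np.mean(q)), sd


def segment_trace(trace: FilamentTrace) -> FilamentTrace:
    """Split a trace into per-filament segments at rupture events.

    A rupture is declared between samples i and i+1 when the length drops
    below ``RUPTURE_DROP_FRACTION`` of its previous value; the new filament's
    first sample (i+1) becomes a segment boundary.  Measurement noise cannot
    trigger the rule: a 50% drop between 250 ms frames dwarfs pixel-scale
    jitter at these speeds.
    """
    if len(trace.times) < 2:
        raise InsufficientDataError("need >= 2 samples to segment a trace")
    lengths = trace.lengths
    boundaries = [
        i + 1
        for i in range(len(lengths) - 1)
        if lengths[i] > 0 and lengths[i + 1] < RUPTURE_DROP_FRACTION * lengths[i]
    ]
    return replace(trace, segment_boundaries=tuple(boundaries))


def extrusion_speed(
    trace: FilamentTrace,
    max_length: float = DEFAULT_MAX_LENGTH,
    max_segments: int = DEFAULT_MAX_SEGMENTS,
) -> SpeedEstimate:
    """Estimate the extrusion speed from a filament trace.

    Speeds are forward finite differences over one frame interval, computed
    within segments only (never across a rupture).  A point enters the
    average when the interval's *starting* length is at most ``max_length``
    and the segment is among the first ``max_segments`` filaments — i.e.
    short filaments, before gravity-driven stretch, up to the second rupture.
    """
    if trace.segment_boundaries is None:
        trace = segment_trace(trace)
    speeds: list[float] = []
    for seg_index, seg in enumerate(trace.segment_slices(), start=1):
        if seg_index > max_segments:
            break
        t = trace.times[seg]
        ell = trace.lengths[seg]
        for i in range(len(ell) - 1):
            if ell[i] <= max_length:
                speeds.append((ell[i + 1] - ell[i]) / (t[i + 1] - t[i]))
    if not speeds:
        raise InsufficientDataError(
            f"no finite-difference points with start length <= {max_length * 1e3:g} mm "
            f"in the first {max_segments} segment(s)"
        )
    arr = np.array(speeds)
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return SpeedEstimate(
        pressure=trace.pressure,
        extrusion_speed_mean=float(np.mean(arr)),
        extrusion_speed_sd=sd,
        points_used=len(arr),
    )


def swell_observations(
    flow_by_pressure: Mapping[float, float],
    speeds: Sequence[SpeedEstimate],
    nozzle: NozzleGeometry,
) -> list[SwellObservation]:
    """Combine flow rates and extrusion speeds into swell observations.

    For each pressure present in both inputs: tau_w from the nozzle force
    balance, R_ex from volume conservation, B = R_ex / R.  Pressures present
    in only one input raise a mismatch error naming the offenders.
    """

    def _key(p: float) -> float:
        return round(float(p), 6)

    flows = {_key(p): q for p, q in flow_by_pressure.items()}
    speed_map = {_key(s.pressure): s for s in speeds}
    only_flow = sorted(set(flows) - set(speed_map))
    only_speed = sorted(set(speed_map) - set(flows))
    if only_flow or only_speed:
        raise MismatchError(
            f"pressure mismatch between flow and speed inputs: "
            f"flow-only={only_flow} Pa, speed-only={only_speed} Pa"
        )
    observations = []
    for p in sorted(flows):
        q = flows[p]
        vex = speed_map[p].extrusion_speed_mean
        tau = wall_shear_stress(nozzle, p)
        rex = extrudate_radius(q, vex)
        observations.append(
            SwellObservation(
                wall_shear_stress=tau,
                swell_ratio=rex / nozzle.inner_radius,
                extrudate_radius=rex,
            )
        )
    return observations
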