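"""Square-lattice scaffold G-code: generation and self-parsing.

The validation construct is a stack of identical square-grid layers: within
each layer, parallel struts along X, then parallel struts along Y, at a fixed
pitch.  The dialect is the minimal common denominator — absolute coordinates
(G90), millimeters (G21), ``G1`` linear extrusion moves at a feed rate in
mm/min, ``G0`` travel moves between struts.  Pneumatic pressure is not a
machine axis, so it and the design parameters ride along as structured
``; key = value`` comments.  :func:`parse_gcode` re-reads this dialect,
which gives every generated file a built-in oracle: the parsed extrusion
path length must equal the design's strut lengths exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import units
from .errors import InvalidInputError, ParseError

__all__ = ["LatticeDesign", "GcodeSummary", "write_gcode", "parse_gcode", "strut_starts"]


@dataclass(frozen=True)
class LatticeDesign:
    """A stacked square-grid scaffold (SI units).

    footprint: (x_size, y_size) of the layer; strut_spacing: pitch between
    parallel struts; printing_speed drives the feed rate; pressure is
    metadata recorded in the file for the operator.
    """

    footprint: tuple[float, float]
    strut_spacing: float
    layers: int = 3
    layer_height: float = 0.41e-3
    printing_speed: float = 1e-3
    pressure: float = 100e3

    def __post_init__(self) -> None:
        fx, fy = self.footprint
        if fx <= 0 or fy <= 0 or self.strut_spacing <= 0:
            raise InvalidInputError("footprint sides and strut_spacing must be > 0")
        if self.strut_spacing > min(fx, fy):
            raise InvalidInputError(
                f"strut_spacing {self.strut_spacing} exceeds footprint {self.footprint}"
            )
        if self.layers < 1 or self.layer_height <= 0 or self.printing_speed <= 0:
            raise InvalidInputError("layers >= 1, layer_height > 0, printing_speed > 0")

    def extrusion_path_length(self) -> float:
        """Total strut length over all layers (m), excluding travel."""
        fx, fy = self.footprint
        n_x_lines = len(strut_starts(fy, self.strut_spacing))  # struts running along X
        n_y_lines = len(strut_starts(fx, self.strut_spacing))
        return self.layers * (n_x_lines * fx + n_y_lines * fy)


def strut_starts(extent: float, spacing: float) -> list[float]:
    """Strut offsets 0, s, 2s, ... <= extent, always including both edges."""
    n = int(np.floor(extent / spacing + 1e-9))
    offsets = [i * spacing for i in range(n + 1)]
    if extent - offsets[-1] > 1e-9:
        offsets.append(extent)
    return offsets


@dataclass(frozen=True)
class GcodeSummary:
    """What parse_gcode recovers: path lengths, feed rate, embedded metadata."""

    extrusion_length: float  # m, sum of G1 move lengths
    travel_length: float  # m, sum of G0 move lengths
    feed_rate: float  # m/s (converted back from mm/min)
    metadata: dict[str, float]


def write_gcode(design: LatticeDesign, path: str | Path) -> None:
    """Write the scaffold toolpath; all coordinates in mm, feed in mm/min."""
    fx, fy = design.footprint
    feed_mm_min = units.m_s_to_mm_min(design.printing_speed)
    lines = [
        "; extruflow square-lattice scaffold",
        f"; pressure_kPa = {units.pa_to_kpa(design.pressure):.9g}",
        f"; printing_speed_mm_s = {units.m_to_mm(design.printing_speed):.9g}",
        f"; strut_spacing_mm = {units.m_to_mm(design.strut_spacing):.9g}",
        f"; layer_height_mm = {units.m_to_mm(design.layer_height):.9g}",
        f"; layers = {design.layers}",
        "G21 ; millimeters",
        "G90 ; absolute coordinates",
    ]

    def fmt(v: float) -> str:
        return f"{units.m_to_mm(v):.4f}"

    for layer in range(design.layers):
        z = (layer + 1) * design.layer_height
        lines.append(f"; layer {layer + 1}")
        lines.append(f"G0 Z{fmt(z)}")
        # struts along X at successive Y offsets, serpentine to shorten travel
        for i, y in enumerate(strut_starts(fy, design.strut_spacing)):
            x_from, x_to = (0.0, fx) if i % 2 == 0 else (fx, 0.0)
            lines.append(f"G0 X{fmt(x_from)} Y{fmt(y)}")
            lines.append(f"G1 X{fmt(x_to)} Y{fmt(y)} F{feed_mm_min:.4f}")
        # struts along Y at successive X offsets
        for i, x in enumerate(strut_starts(fx, design.strut_spacing)):
            y_from, y_to = (0.0, fy) if i % 2 == 0 else (fy, 0.0)
            lines.append(f"G0 X{fmt(x)} Y{fmt(y_from)}")
            lines.append(f"G1 X{fmt(x)} Y{fmt(y_to)} F{feed_mm_min:.4f}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_gcode(path: str | Path) -> GcodeSummary:
    """Re-read a generated file: path lengths by move type, feed rate, metadata."""
    pos = {"X": 0.0, "Y": 0.0, "Z": 0.0}
    extrusion = 0.0
    travel = 0.0
    feed_rates: set[float] = set()
    metadata: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(";"):
            if "=" in line:
                key, _, value = line[1:].partition("=")
                try:
                    metadata[key.strip()] = float(value.strip())
                except ValueError:
                    pass
            continue
        parts = line.split(";")[0].split()
        cmd = parts[0]
        if cmd in ("G21", "G90"):
            continue
        if cmd not in ("G0", "G1"):
            raise ParseError(f"unsupported G-code command {cmd!r} in line {raw!r}")
        new = dict(pos)
        for word in parts[1:]:
            axis, value = word[0], word[1:]
            if axis in pos:
                new[axis] = units.mm_to_m(float(value))
            elif axis == "F":
                feed_rates.add(units.mm_min_to_m_s(float(value)))
            else:
                raise ParseError(f"unknown word {word!r} in line {raw!r}")
        dist = float(
            np.sqrt(sum((new[a] - pos[a]) ** 2 for a in ("X", "Y", "Z")))
        )
        if cmd == "G1":
            extrusion += dist
        else:
            travel += dist
        pos = new
    if len(feed_rates) > 1:
        raise ParseError(f"multiple feed rates found: {sorted(feed_rates)}")
    return GcodeSummary(
        extrusion_length=extrusion,
        travel_length=travel,
        feed_rate=feed_rates.pop() if feed_rates else 0.0,
        metadata=metadata,
    )
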