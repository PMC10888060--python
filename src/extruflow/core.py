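"""Closed-form hydrodynamics of pneumatic extrusion through a cylindrical nozzle.

The model stack, from material to deposited strand:

* **Rheology.** The bioink is a Power Law (Ostwald-de Waele) fluid,
  ``eta = K * gamma_dot**(n - 1)``, with consistency index ``K`` (Pa s^n)
  and flow index ``n`` (shear-thinning for n < 1).

* **Flow.** Steady laminar flow of such a fluid through a cylinder of inner
  radius ``R`` and length ``L`` under pressure drop ``dP`` gives the
  volumetric flow rate

      Q = pi * (dP / (2 K L))**(1/n) * R**(3 + 1/n) / (3 + 1/n)

  which reduces to Hagen-Poiseuille, ``pi dP R**4 / (8 K L)``, at n = 1.

* **Wall shear stress.** ``tau_w = R dP / (2 L)`` — the maximal stress the
  suspended cells experience, and the abscissa of the swell law.

* **Extrudate swell (Barus effect).** The emerging strand is thicker than
  the nozzle bore; the swell ratio ``B = R_ex / R`` is modelled empirically
  as ``B = c1 + c2 * tau_w**beta``.

* **Volume conservation.** A strand advancing at speed ``v`` and carrying
  flow ``Q`` has radius ``r = sqrt(Q / (pi v))``; the same identity links the
  free-hanging extrudate (``v_ex``, ``R_ex``) and the deposited filament
  (``v_p``, ``R_p``).

All quantities are SI (Pa, m, s, m^3/s).  Use :mod:`extruflow.units` at the
boundary.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .errors import InvalidInputError

__all__ = [
    "NozzleGeometry",
    "PowerLawRheology",
    "ShearState",
    "SwellLaw",
    "SwellObservation",
    "PrintPlan",
    "Regime",
    "flow_rate",
    "wall_shear_stress",
    "shear_state",
    "wall_shear_rate",
    "swell_ratio",
    "extrudate_radius",
    "printed_radius",
    "printing_speed_for_radius",
    "poi",
]


def _require_positive(**quantities: float) -> None:
    for name, value in quantities.items():
        if not value > 0:
            raise InvalidInputError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class NozzleGeometry:
    """Cylindrical nozzle: inner radius and length, in meters.

    The default factory :meth:`gauge_22` is the blunt 22G half-inch needle
    common on pneumatic print heads (inner diameter 0.413 mm, length 12.7 mm).
    """

    inner_radius: float
    length: float

    def __post_init__(self) -> None:
        _require_positive(inner_radius=self.inner_radius, length=self.length)
        if not self.length > self.inner_radius:
            raise InvalidInputError(
                f"nozzle length {self.length} must exceed inner radius {self.inner_radius}"
            )

    @classmethod
    def gauge_22(cls) -> "NozzleGeometry":
        return cls(inner_radius=0.2065e-3, length=12.7e-3)


@dataclass(frozen=True)
class PowerLawRheology:
    """Power Law material constants K (Pa s^n) and n (dimensionless).

    n = 1 (Newtonian) is admitted as a limiting case so the model can be
    checked against Hagen-Poiseuille; shear-thinning bioinks have n < 1.
    """

    consistency_index: float
    power_law_index: float

    def __post_init__(self) -> None:
        _require_positive(consistency_index=self.consistency_index)
        n = self.power_law_index
        if not (0 < n <= 1):
            raise InvalidInputError(f"power_law_index must be in (0, 1], got {n!r}")


@dataclass(frozen=True)
class ShearState:
    """A (shear rate, viscosity) pair consistent with a Power Law material."""

    shear_rate: float
    viscosity: float

    def __post_init__(self) -> None:
        if self.shear_rate < 0:
            raise InvalidInputError(f"shear_rate must be >= 0, got {self.shear_rate!r}")
        _require_positive(viscosity=self.viscosity)


@dataclass(frozen=True)
class SwellLaw:
    """Empirical swell law B(tau_w) = offset + amplitude * tau_w**exponent.

    ``offset`` (c1) is the low-stress swell ratio, ``amplitude`` (c2, units
    Pa^-exponent) scales the stress-driven growth and ``exponent`` (beta) its
    steepness.  amplitude = 0 gives a stress-independent swell.
    """

    offset: float
    amplitude: float
    exponent: float

    def __post_init__(self) -> None:
        _require_positive(offset=self.offset, exponent=self.exponent)
        if self.amplitude < 0:
            raise InvalidInputError(f"amplitude must be >= 0, got {self.amplitude!r}")


@dataclass(frozen=True)
class SwellObservation:
    """One measured swell point: wall shear stress, swell ratio, extrudate radius."""

    wall_shear_stress: float
    swell_ratio: float
    extrudate_radius: float

    def __post_init__(self) -> None:
        _require_positive(
            wall_shear_stress=self.wall_shear_stress,
            swell_ratio=self.swell_ratio,
            extrudate_radius=self.extrudate_radius,
        )


class Regime(str, enum.Enum):
    """How the print-head speed relates to the natural extrusion speed.

    ``stretched``: v_p > v_ex, the deposited strand is thinner than the free
    extrudate; ``compressed``: v_p < v_ex, material piles up (coiling risk);
    ``matched``: the speeds agree and the strand lands at its swollen radius.
    """

    STRETCHED = "stretched"
    MATCHED = "matched"
    COMPRESSED = "compressed"


@dataclass(frozen=True)
class PrintPlan:
    """A planned deposition: pressure, target radius, required speed, POI."""

    pressure: float
    printed_radius: float
    printing_speed: float
    poi: float
    regime_flag: Regime

    def __post_init__(self) -> None:
        _require_positive(
            pressure=self.pressure,
            printed_radius=self.printed_radius,
            printing_speed=self.printing_speed,
            poi=self.poi,
        )


def flow_rate(rheology: PowerLawRheology, nozzle: NozzleGeometry, pressure: float) -> float:
    """Volumetric flow rate Q (m^3/s) of a Power Law fluid through the nozzle.

    Q = pi * (dP / (2 K L))**(1/n) * R**(3 + 1/n) / (3 + 1/n); strictly
    increasing in pressure, and steeply so for shear-thinning fluids
    (Q ~ dP**(1/n)).
    """
    _require_positive(pressure=pressure)
    K = rheology.consistency_index
    n = rheology.power_law_index
    R = nozzle.inner_radius
    L = nozzle.length
    inv_n = 1.0 / n
    return math.pi * (pressure / (2.0 * K * L)) ** inv_n * R ** (3.0 + inv_n) / (3.0 + inv_n)


def wall_shear_stress(nozzle: NozzleGeometry, pressure: float) -> float:
    """Shear stress at the nozzle wall, tau_w = R dP / (2 L) (Pa).

    Linear in pressure and independent of the material: it follows from the
    axial force balance alone.
    """
    _require_positive(pressure=pressure)
    return nozzle.inner_radius * pressure / (2.0 * nozzle.length)


def shear_state(rheology: PowerLawRheology, shear_rate: float) -> ShearState:
    """Viscosity at a given shear rate: eta = K * gamma_dot**(n-1)."""
    if shear_rate <= 0:
        raise InvalidInputError(
            f"shear_rate must be > 0 (viscosity diverges as gamma_dot -> 0 for n < 1), "
            f"got {shear_rate!r}"
        )
    eta = rheology.consistency_index * shear_rate ** (rheology.power_law_index - 1.0)
    return ShearState(shear_rate=shear_rate, viscosity=eta)


def wall_shear_rate(rheology: PowerLawRheology, wall_stress: float) -> float:
    """Inverse of the constitutive law: gamma_dot_w = (tau_w / K)**(1/n),
    so that K * gamma_dot_w**n == tau_w."""
    _require_positive(wall_stress=wall_stress)
    return (wall_stress / rheology.consistency_index) ** (1.0 / rheology.power_law_index)


def swell_ratio(law: SwellLaw, wall_stress: float) -> float:
    """Extrudate swell ratio B = c1 + c2 * tau_w**beta (dimensionless)."""
    _require_positive(wall_shear_stress=wall_stress)
    return law.offset + law.amplitude * wall_stress ** law.exponent


def extrudate_radius(flow: float, extrusion_speed: float) -> float:
    """Radius of the free extrudate by volume conservation: sqrt(Q / (pi v_ex))."""
    _require_positive(flow=flow, extrusion_speed=extrusion_speed)
    return math.sqrt(flow / (math.pi * extrusion_speed))


def printed_radius(flow: float, printing_speed: float) -> float:
    """Radius of the deposited strand at print-head speed v_p: sqrt(Q / (pi v_p))."""
    _require_positive(flow=flow, printing_speed=printing_speed)
    return math.sqrt(flow / (math.pi * printing_speed))


def printing_speed_for_radius(flow: float, target_radius: float) -> float:
    """Print-head speed that deposits a strand of the target radius: Q / (pi R_p^2).

    Exact inverse of :func:`printed_radius`.
    """
    _require_positive(flow=flow, target_radius=target_radius)
    return flow / (math.pi * target_radius**2)


def poi(printed_radius_m: float, wall_stress: float) -> float:
    """Parameter optimization index, POI = 1 / (2 R_p tau_w), units 1/(Pa m).

    The ratio of print accuracy (finer strands, smaller R_p) to the shear
    stress the cells endure; higher is better.  Implemented literally with no
    renormalization, so values are comparable only within one unit system.
    """
    _require_positive(printed_radius=printed_radius_m, wall_shear_stress=wall_stress)
    return 1.0 / (2.0 * printed_radius_m * wall_stress)
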