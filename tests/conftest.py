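"""Shared fixtures: the reference hydrogel's fitted constants and nozzle.

The reference material is the Cellink Start hydrogel extruded through a 22G
half-inch blunt needle; its fitted constants anchor the worked examples.
"""

import pytest

from extruflow import NozzleGeometry, PowerLawRheology, SwellLaw


@pytest.fixture(scope="session")
def nozzle_22g() -> NozzleGeometry:
    return NozzleGeometry.gauge_22()


@pytest.fixture(scope="session")
def reference_rheology() -> PowerLawRheology:
    """Fitted power-law constants of the reference hydrogel."""
    return PowerLawRheology(consistency_index=222.0, power_law_index=0.23)


@pytest.fixture(scope="session")
def reference_swell_law() -> SwellLaw:
    """Fitted empirical swell constants of the reference hydrogel."""
    return SwellLaw(offset=1.57, amplitude=1.38e-10, exponent=3.15)
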