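"""Parameter recovery for the flow model and the empirical swell law."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from extruflow import (
    FlowRateDataset,
    NozzleGeometry,
    PowerLawRheology,
    SwellLaw,
    SwellObservation,
    fit_power_law,
    fit_swell_law,
    flow_rate,
    swell_ratio,
    wall_shear_stress,
)
from extruflow.errors import InsufficientDataError

PRESSURES = [p * 1e3 for p in range(70, 131, 10)]


def make_flow_dataset(rheology, nozzle, noise_cv=0.0, replicates=1, rng=None):
    records = []
    for p in PRESSURES:
        q = flow_rate(rheology, nozzle, p)
        if noise_cv > 0:
            flows = q * (1 + rng.normal(0, noise_cv, size=replicates))
        else:
            flows = np.full(replicates, q)
        records.append((p, list(flows)))
    return FlowRateDataset(records=records, nozzle=nozzle)


def make_swell_observations(law, nozzle, noise_sd=0.0, rng=None):
    observations = []
    for p in PRESSURES:
        tau = wall_shear_stress(nozzle, p)
        b = swell_ratio(law, tau)
        if noise_sd > 0:
            b = b + rng.normal(0, noise_sd)
        observations.append(
            SwellObservation(wall_shear_stress=tau, swell_ratio=b,
                             extrudate_radius=b * nozzle.inner_radius)
        )
    return observations


class TestFitPowerLaw:
    def test_noiseless_recovery(self, reference_rheology, nozzle_22g):
        data = make_flow_dataset(reference_rheology, nozzle_22g)
        rheology, fit = fit_power_law(data)
        assert rheology.consistency_index == pytest.approx(222.0, rel=1e-6)
        assert rheology.power_law_index == pytest.approx(0.23, rel=1e-6)
        assert fit.converged
        assert fit.sse < 1e-25

    def test_newtonian_data_recovers_unit_index(self, nozzle_22g):
        rheology = PowerLawRheology(consistency_index=3.0, power_law_index=1.0)
        data = make_flow_dataset(rheology, nozzle_22g)
        fitted, _ = fit_power_law(data)
        assert fitted.power_law_index == pytest.approx(1.0, abs=1e-6)
        assert fitted.consistency_index == pytest.approx(3.0, rel=1e-4)

    def test_noisy_recovery_monte_carlo(self, reference_rheology, nozzle_22g):
        """5% multiplicative noise, 5 replicates: the flow index is pinned
        to within a few thousandths in the median."""
        errors = []
        rng = np.random.default_rng(20240103)
        for _ in range(100):
            data = make_flow_dataset(
                reference_rheology, nozzle_22g, noise_cv=0.05, replicates=5, rng=rng
            )
            fitted, _ = fit_power_law(data)
            errors.append(abs(fitted.power_law_index - 0.23))
        assert np.median(errors) < 0.03

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        k=st.floats(1.0, 1e3),
        n=st.floats(0.15, 1.0),
    )
    def test_recovers_any_generator(self, k, n):
        rheology = PowerLawRheology(consistency_index=k, power_law_index=n)
        nozzle = NozzleGeometry.gauge_22()
        fitted, fit = fit_power_law(make_flow_dataset(rheology, nozzle))
        assert fitted.consistency_index == pytest.approx(k, rel=1e-4)
        assert fitted.power_law_index == pytest.approx(n, rel=1e-4)

    def test_objective_never_worse_than_start(self, reference_rheology, nozzle_22g):
        rng = np.random.default_rng(7)
        data = make_flow_dataset(reference_rheology, nozzle_22g, noise_cv=0.1,
                                 replicates=5, rng=rng)
        _, fit = fit_power_law(data)
        start = PowerLawRheology(
            consistency_index=fit.initial_guess["consistency_index"],
            power_law_index=fit.initial_guess["power_law_index"],
        )
        sse_start = sum(
            (qm - flow_rate(start, nozzle_22g, p)) ** 2
            for p, qm in zip(data.pressures, data.mean_flows)
        )
        assert fit.sse <= sse_start + 1e-30

    def test_requires_two_distinct_pressures(self, nozzle_22g):
        with pytest.raises(InsufficientDataError):
            FlowRateDataset(records=[(100e3, [1e-9]), (100e3, [1.1e-9])], nozzle=nozzle_22g)


class TestFitSwellLaw:
    def test_noiseless_recovery(self, reference_swell_law, nozzle_22g):
        observations = make_swell_observations(reference_swell_law, nozzle_22g)
        law, fit = fit_swell_law(observations)
        assert law.offset == pytest.approx(1.57, rel=1e-4)
        assert law.amplitude == pytest.approx(1.38e-10, rel=1e-4)
        assert law.exponent == pytest.approx(3.15, rel=1e-4)
        assert fit.converged

    def test_flat_swell_degenerates_gracefully(self, nozzle_22g):
        law = SwellLaw(offset=1.6, amplitude=0.0, exponent=3.0)
        observations = make_swell_observations(law, nozzle_22g)
        fitted, _ = fit_swell_law(observations)
        assert fitted.offset == pytest.approx(1.6, abs=1e-4)
        # the stress-driven term must be negligible over the observed range
        tau_max = max(o.wall_shear_stress for o in observations)
        assert fitted.amplitude * tau_max**fitted.exponent < 1e-3

    def test_noisy_offset_recovery_monte_carlo(self, reference_swell_law, nozzle_22g):
        """2% additive noise on B: the offset c1 stays within 0.05 in the median."""
        rng = np.random.default_rng(20240104)
        errors = []
        for _ in range(100):
            observations = make_swell_observations(
                reference_swell_law, nozzle_22g, noise_sd=0.02, rng=rng
            )
            law, _ = fit_swell_law(observations)
            errors.append(abs(law.offset - 1.57))
        assert np.median(errors) < 0.05

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        c1=st.floats(1.0, 2.5),
        log_c2=st.floats(-12, -7),
        beta=st.floats(1.5, 4.0),
    )
    def test_recovers_any_generator(self, c1, log_c2, beta):
        law = SwellLaw(offset=c1, amplitude=10**log_c2, exponent=beta)
        nozzle = NozzleGeometry.gauge_22()
        observations = make_swell_observations(law, nozzle)
        # only well-identified generators: the power term must actually move B
        tau_max = max(o.wall_shear_stress for o in observations)
        if law.amplitude * tau_max**beta < 1e-2:
            return
        fitted, _ = fit_swell_law(observations)
        assert fitted.offset == pytest.approx(c1, rel=1e-3, abs=1e-3)
        assert fitted.exponent == pytest.approx(beta, rel=1e-2)

    def test_requires_three_distinct_stresses(self):
        observations = [
            SwellObservation(wall_shear_stress=500.0, swell_ratio=1.6, extrudate_radius=3e-4),
            SwellObservation(wall_shear_stress=800.0, swell_ratio=1.8, extrudate_radius=3.5e-4),
        ]
        with pytest.raises(InsufficientDataError):
            fit_swell_law(observations)

    def test_fitted_parameters_satisfy_invariants(self, reference_swell_law, nozzle_22g):
        rng = np.random.default_rng(11)
        observations = make_swell_observations(
            reference_swell_law, nozzle_22g, noise_sd=0.05, rng=rng
        )
        law, _ = fit_swell_law(observations)  # SwellLaw validates on construction
        assert law.offset > 0 and law.amplitude >= 0 and law.exponent > 0
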