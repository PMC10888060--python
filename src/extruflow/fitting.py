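"""Nonlinear least-squares recovery of material and swell constants.

Both fits minimize an unweighted sum of squared residuals on the natural
scale of the data (flow rate Q, swell ratio B) with the derivative-free
Nelder-Mead simplex, seeded from a closed-form initial guess:

* ``fit_power_law`` — (K, n) from per-pressure mean flow rates.  The log-log
  linearization of Q ~ dP**(1/n) gives the start (slope = 1/n, intercept
  fixes K); the simplex then refines on Q itself.
* ``fit_swell_law`` — (c1, c2, beta) from (tau_w, B) observations.  c2 and
  beta are kept positive by fitting the stress-driven term as
  exp(a + beta * log(tau_w / tau_ref)) with beta in log-space; tau_ref is the
  largest observed stress, which keeps the amplitude parameter well scaled
  even though c2 itself spans many decades.

Replicate flows are averaged before fitting; replicate scatter is reported
(FlowRateDataset keeps it) but not used as weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .core import NozzleGeometry, PowerLawRheology, SwellLaw, SwellObservation
from .errors import InsufficientDataError, InvalidInputError

__all__ = ["FlowRateDataset", "FitResult", "fit_power_law", "fit_swell_law"]

_MAX_ITER = 10_000
_TOL = 1e-10


@dataclass(frozen=True)
class FlowRateDataset:
    """Per-pressure replicate flow rates (SI) plus the nozzle they came from.

    records: sequence of (pressure_Pa, [flow_m3_s, ...]) with >= 1 replicate
    each and >= 2 distinct pressures overall.
    """

    records: tuple[tuple[float, tuple[float, ...]], ...]
    nozzle: NozzleGeometry

    def __init__(
        self,
        records: Sequence[tuple[float, Sequence[float]]],
        nozzle: NozzleGeometry,
    ) -> None:
        frozen = tuple((float(p), tuple(float(q) for q in flows)) for p, flows in records)
        for p, flows in frozen:
            if p <= 0:
                raise InvalidInputError(f"pressure must be > 0, got {p}")
            if not flows:
                raise InsufficientDataError(f"pressure {p} Pa has no flow replicates")
            if any(q <= 0 for q in flows):
                raise InvalidInputError(f"non-positive flow at pressure {p} Pa")
        if len({p for p, _ in frozen}) < 2:
            raise InsufficientDataError(
                "need >= 2 distinct pressures to constrain (K, n), "
                f"got {len({p for p, _ in frozen})}"
            )
        object.__setattr__(self, "records", frozen)
        object.__setattr__(self, "nozzle", nozzle)

    @property
    def pressures(self) -> np.ndarray:
        return np.array([p for p, _ in self.records])

    @property
    def mean_flows(self) -> np.ndarray:
        return np.array([np.mean(flows) for _, flows in self.records])

    @property
    def flow_sds(self) -> np.ndarray:
        """Sample SD per pressure (0 for a single replicate)."""
        return np.array(
            [np.std(flows, ddof=1) if len(flows) > 1 else 0.0 for _, flows in self.records]
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a simplex fit: objective, convergence diagnostics, start point."""

    parameters: dict[str, float]
    sse: float
    converged: bool
    iterations: int
    initial_guess: dict[str, float] = field(default_factory=dict)


def _power_law_initial_guess(pressures: np.ndarray, q_mean: np.ndarray, nozzle: NozzleGeometry):
    # log Q = const + (1/n) log dP  =>  slope of the log-log regression is 1/n
    slope, intercept = np.polyfit(np.log(pressures), np.log(q_mean), 1)
    n0 = 1.0 / slope if slope > 0 else 1.0
    n0 = min(max(n0, 1e-3), 1.0)
    # with n fixed, each point solves for K; combine with the geometric mean
    R, L = nozzle.inner_radius, nozzle.length
    inv_n = 1.0 / n0
    coef = math.pi * R ** (3.0 + inv_n) / (3.0 + inv_n)
    k_each = pressures / (2.0 * L) * (coef / q_mean) ** n0
    k0 = float(np.exp(np.mean(np.log(k_each))))
    return k0, n0


def fit_power_law(data: FlowRateDataset) -> tuple[PowerLawRheology, FitResult]:
    """Recover (K, n) by least squares on per-pressure mean flow rates.

    Minimizes sum_p (Qbar_p - Q_model(dP_p; K, n))**2 over K > 0, n > 0,
    simplex-refined from the log-log start.  If the optimizer stops at the
    Newtonian boundary within 1e-6 the index is snapped to exactly 1.
    """
    pressures = data.pressures
    q_mean = data.mean_flows
    k0, n0 = _power_law_initial_guess(pressures, q_mean, data.nozzle)
    scale = float(np.max(q_mean))  # keeps the objective O(1) regardless of units

    R, L = data.nozzle.inner_radius, data.nozzle.length

    def objective(theta: np.ndarray) -> float:
        log_k, log_n = theta
        K, n = math.exp(log_k), math.exp(log_n)
        if n > 2.0:  # far outside the physical range; steer the simplex back
            return 1e6 * n
        inv_n = 1.0 / n
        # same closed form as core.flow_rate, vectorized over the pressure grid
        model = math.pi * (pressures / (2.0 * K * L)) ** inv_n * R ** (3.0 + inv_n) / (3.0 + inv_n)
        return float(np.sum(((q_mean - model) / scale) ** 2))

    x0 = np.array([math.log(k0), math.log(n0)])
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": _TOL, "maxiter": _MAX_ITER, "maxfev": _MAX_ITER},
    )
    K_hat, n_hat = math.exp(res.x[0]), math.exp(res.x[1])
    if abs(n_hat - 1.0) < 1e-6:
        n_hat = 1.0
    converged = bool(res.success) and 0 < n_hat <= 1
    n_hat = min(n_hat, 1.0)
    rheology = PowerLawRheology(consistency_index=K_hat, power_law_index=n_hat)
    fit = FitResult(
        parameters={"consistency_index": K_hat, "power_law_index": n_hat},
        sse=float(res.fun) * scale**2,
        converged=converged,
        iterations=int(res.nit),
        initial_guess={"consistency_index": k0, "power_law_index": n0},
    )
    return rheology, fit


def fit_swell_law(observations: Sequence[SwellObservation]) -> tuple[SwellLaw, FitResult]:
    """Recover (c1, c2, beta) of B = c1 + c2 tau_w**beta by least squares.

    Requires >= 3 distinct wall shear stresses (three parameters).  c2 >= 0
    and beta > 0 are enforced through the parameterization, not by clipping.
    """
    tau = np.array([o.wall_shear_stress for o in observations], dtype=float)
    b_obs = np.array([o.swell_ratio for o in observations], dtype=float)
    if len(np.unique(tau)) < 3:
        raise InsufficientDataError(
            f"need >= 3 observations with distinct wall shear stress, got {len(np.unique(tau))}"
        )

    tau_ref = float(np.max(tau))
    log_tau_rel = np.log(tau / tau_ref)

    # start: c1 at the smallest observed swell, beta = 3, amplitude from the
    # largest-stress point (where the power term dominates most)
    c1_0 = float(np.min(b_obs))
    beta_0 = 3.0
    amp_ref0 = max(float(b_obs[np.argmax(tau)] - c1_0), 1e-6)
    c2_0 = amp_ref0 / tau_ref**beta_0

    def objective(theta: np.ndarray) -> float:
        c1, log_amp, log_beta = theta
        beta = math.exp(log_beta)
        model = c1 + np.exp(log_amp + beta * log_tau_rel)
        return float(np.sum((b_obs - model) ** 2))

    x0 = np.array([c1_0, math.log(amp_ref0), math.log(beta_0)])
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": _TOL, "maxiter": _MAX_ITER, "maxfev": _MAX_ITER},
    )
    c1_hat = float(res.x[0])
    beta_hat = math.exp(res.x[2])
    c2_hat = math.exp(res.x[1]) / tau_ref**beta_hat
    converged = bool(res.success) and c1_hat > 0
    law = SwellLaw(offset=c1_hat, amplitude=c2_hat, exponent=beta_hat)
    fit = FitResult(
        parameters={"offset": c1_hat, "amplitude": c2_hat, "exponent": beta_hat},
        sse=float(res.fun),
        converged=converged,
        iterations=int(res.nit),
        initial_guess={"offset": c1_0, "amplitude": c2_0, "exponent": beta_0},
    )
    return law, fit
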