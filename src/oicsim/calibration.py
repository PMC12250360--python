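"""Steady-state calibration of the cAMP production law.

The cAMP balance  d(cAMP)/dt = -k1*cAMP + k2*H(AC_on)  with the Hill term
H(a) = (a/EC50)^n / (1 + (a/EC50)^n)  has the closed-form steady state

    cAMP* = (k2/k1) * H(AC_on).

Steady-state measurements constrain only the ratio k2/k1 together with
(EC50, n): scaling k1 and k2 jointly leaves cAMP* unchanged.  The
inference therefore holds k1 fixed (default 6.1e-3 ms^-1) and fits k2,
EC50 and n by weighted least squares with multi-start.

The closed form itself is scale-agnostic in its activation argument; the
calibration layer feeds it the activated-AC readout expressed in PERCENT
of the AC pool (0-100), the scale on which activation dose-response data
are reported.  This matters for identifiability: with a reference
midpoint of 135, activation fractions (<= 1) would sit so deep in the
power-law regime that EC50 and k2 would be exactly degenerate, whereas
percent-scale readouts approach the midpoint and constrain it.

A synthetic calibration-data generator emulates cAMP-accumulation
dose-response measurements at several receptor densities with
multiplicative lognormal noise, so the inference stage is testable
without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CalibrationPoint", "CampParams", "IdentifiabilityError",
    "steady_state_camp", "infer_camp_params",
    "generate_synthetic_calibration",
]


class IdentifiabilityError(RuntimeError):
    """Raised when the calibration design cannot constrain the Hill law."""


#: activation readouts enter the calibration in percent of the AC pool
ACTIVATION_SCALE = 100.0


@dataclass(frozen=True)
class CampParams:
    """Parameters of the cAMP production/degradation pair: degradation
    rate k1 (ms^-1), production scale k2, Hill midpoint EC50 (activated-AC
    fraction units) and Hill coefficient n."""

    k1: float = 6.1e-3
    k2: float = 141.3
    EC50_hill: float = 135.0
    n_hill: float = 2.44

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.EC50_hill, self.n_hill) <= 0:
            raise ValueError("all cAMP parameters must be positive")


@dataclass(frozen=True)
class CalibrationPoint:
    """One measurement: serotonin concentration (uM), receptor density
    (uM) and the measured cAMP accumulation (arbitrary units)."""

    serotonin_concentration: float
    receptor_density: float
    measured_camp: float

    def __post_init__(self) -> None:
        if (self.serotonin_concentration < 0 or self.receptor_density < 0
                or self.measured_camp < 0):
            raise ValueError("calibration points must be non-negative")


def steady_state_camp(ac_on, params: CampParams):
    """Closed-form steady-state cAMP level for an activated-AC fraction."""
    a = np.asarray(ac_on, dtype=float)
    if (a < 0).any():
        raise ValueError("ac_on must be >= 0")
    h = (a / params.EC50_hill) ** params.n_hill
    out = (params.k2 / params.k1) * h / (1.0 + h)
    return float(out) if np.isscalar(ac_on) else out


def generate_synthetic_calibration(
    true_params: CampParams,
    receptor_densities: Sequence[float],
    serotonin_grid: Sequence[float],
    noise_cv: float = 0.05,
    seed: int = 0,
    ac_on_model: Callable[[float, float], float] | None = None,
) -> list[CalibrationPoint]:
    """Synthetic stand-in for a cAMP-vs-serotonin calibration experiment.

    For each receptor density and serotonin level the activated-AC
    fraction is computed by ``ac_on_model`` (defaults to the simulated
    serotonin-arm quasi-steady state), expressed in percent, mapped
    through the steady-state cAMP law, and perturbed by multiplicative
    lognormal noise with coefficient of variation ``noise_cv``.
    Deterministic for a fixed seed.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if ac_on_model is None:
        from .doseresponse import agonist_ac_on_model
        ac_on_model = agonist_ac_on_model()
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv ** 2))
    points: list[CalibrationPoint] = []
    for density in receptor_densities:
        for serotonin in serotonin_grid:
            ac_on = ACTIVATION_SCALE * ac_on_model(float(serotonin),
                                                   float(density))
            camp = steady_state_camp(ac_on, true_params)
            if noise_cv > 0:
                # lognormal with unit mean and the requested CV
                camp *= rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma)
            points.append(CalibrationPoint(float(serotonin), float(density),
                                           float(camp)))
    return points


def infer_camp_params(
    points: Sequence[CalibrationPoint],
    ac_on_model: Callable[[float, float], float],
    k1_fixed: float = 6.1e-3,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[CampParams, dict]:
    """Fit (k2, EC50, n) of the steady-state cAMP law to measurements.

    k1 is held fixed because steady-state data constrain only k2/k1.
    Weighted least squares (weights 1/measurement, matching a
    constant-CV noise model) in log-parameter space, with ``n_starts``
    multi-starts drawn log-uniformly around the initial guess.  Returns
    the parameters plus diagnostics (residuals, approximate standard
    errors, the achieved cost).
    """
    if len(points) < 6:
        raise IdentifiabilityError("need at least six calibration points")
    ac_on = ACTIVATION_SCALE * np.array([
        ac_on_model(p.serotonin_concentration, p.receptor_density)
        for p in points
    ])
    y = np.array([p.measured_camp for p in points])
    spread = ac_on.max() - ac_on.min()
    if spread <= 1e-9 * max(ac_on.max(), 1e-30):
        raise IdentifiabilityError(
            "all points share the same activated-AC fraction; "
            "the design carries no dose variation"
        )
    pos = y[y > 0]
    if pos.size < 4:
        raise IdentifiabilityError("too few non-zero measurements")
    w = 1.0 / np.maximum(y, pos.min())

    # theta = log10([k2, EC50, n])
    def residual(theta: np.ndarray) -> np.ndarray:
        k2, ec50, n = 10.0 ** theta
        h = (ac_on / ec50) ** n
        model = (k2 / k1_fixed) * h / (1.0 + h)
        return w * (model - y)

    a_mid = math.sqrt(ac_on.max() * max(ac_on[ac_on > 0].min(), 1e-12))
    guess = np.array([math.log10(max(y.max() * k1_fixed, 1e-12)),
                      math.log10(a_mid), 0.0])
    lo = guess + np.array([-6, -6, math.log10(0.05)])
    hi = guess + np.array([6, 8, math.log10(20.0)])
    rng = np.random.default_rng(seed)
    starts = [guess] + [
        rng.uniform(guess - 1.5, guess + 1.5) for _ in range(n_starts - 1)
    ]
    best = None
    for theta0 in starts:
        sol = least_squares(residual, np.clip(theta0, lo, hi),
                            bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
    k2, ec50, n = 10.0 ** best.x
    params = CampParams(k1=k1_fixed, k2=k2, EC50_hill=ec50, n_hill=n)

    # delta-method standard errors on the log10 parameters
    J = best.jac
    dof = max(len(y) - 3, 1)
    s2 = 2 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        log_se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        log_se = np.full(3, np.nan)
    diagnostics = {
        "residuals": residual(best.x),
        "cost": float(best.cost),
        "log10_se": {"k2": float(log_se[0]), "EC50_hill": float(log_se[1]),
                     "n_hill": float(log_se[2])},
        "ci95_log10": {
            name: (float(best.x[i] - 1.96 * log_se[i]),
                   float(best.x[i] + 1.96 * log_se[i]))
            for i, name in enumerate(("k2", "EC50_hill", "n_hill"))
        },
        "ac_on": ac_on,
    }
    return params, diagnostics
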