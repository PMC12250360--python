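"""Shared fixtures and the independent fixed-step RK4 oracle."""

from __future__ import annotations

import numpy as np
import pytest

import oicsim as oc
from oicsim.experiments import TreatmentScenario, drug_free_equilibrium, run_acute_treatment


@pytest.fixture(scope="session")
def drugs():
    return oc.default_drugs()


@pytest.fixture(scope="session")
def full_network(drugs):
    return oc.build_network(drug=drugs["Morphine"])


@pytest.fixture(scope="session")
def baseline_state():
    """Drug-free equilibrium of the full network after 24 h."""
    return drug_free_equilibrium()


@pytest.fixture(scope="session")
def morphine_acute(drugs, baseline_state):
    """Acute 4.7 uM Morphine scenario: (trajectory, report)."""
    scenario = TreatmentScenario(drugs["Morphine"])
    return run_acute_treatment(scenario, baseline_state=baseline_state)


def rk4_integrate(network, x0, t_end, dt):
    """Independent fixed-step classic Runge-Kutta integration of
    dx/dt = S*pi(x), used as the oracle against the adaptive solver."""
    S = oc.stoichiometric_matrix(network).astype(float)
    compiled = network.compiled()

    def f(t, x):
        return S @ compiled.propensities(np.clip(x, 0.0, None), t)

    n_steps = int(np.ceil(t_end / dt))
    x = np.array(x0, dtype=float)
    t = 0.0
    for _ in range(n_steps):
        h = min(dt, t_end - t)
        k1 = f(t, x)
        k2 = f(t + h / 2, x + h / 2 * k1)
        k3 = f(t + h / 2, x + h / 2 * k2)
        k4 = f(t + h, x + h * k3)
        x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
    return x
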