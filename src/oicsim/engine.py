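"""Deterministic integration of the reaction-rate equations.

dx/dt = S * pi(x, t) is integrated with LSODA (the system is stiff: rate
constants span 0.2 uM^-1 ms^-1 down to 1e-8 ms^-1 and horizons reach two
weeks of simulated time).  The output grid is log-dense over the first
simulated hour, where binding transients live, and hourly afterwards, so
that recovery times interpolated from the grid are accurate to well under
a minute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import ReactionNetwork, conserved_totals

__all__ = [
    "SolverOptions", "Trajectory", "IntegrationError", "SteadyStateError",
    "integrate", "ac_on_fraction", "receptor_occupancy", "steady_state",
    "HOUR_MS", "DAY_MS",
]

HOUR_MS = 3.6e6
DAY_MS = 24 * HOUR_MS

#: negative excursions larger than this (uM) are an error, smaller ones
#: are clipped to zero
NEGATIVE_TOL = 1e-12


class IntegrationError(RuntimeError):
    """Solver failure; carries the last valid time/state reached."""

    def __init__(self, message: str, t_last: float, state_last: np.ndarray):
        super().__init__(message)
        self.t_last = t_last
        self.state_last = state_last


class SteadyStateError(RuntimeError):
    """No fixed point found within the allowed horizon."""


@dataclass(frozen=True)
class SolverOptions:
    rel_tol: float = 1e-8
    abs_tol: float = 1e-14
    max_step: float = np.inf     # ms
    method_hint: str = "stiff"   # stiff -> LSODA, auto -> RK45 fallback

    def __post_init__(self) -> None:
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be positive")

    @property
    def method(self) -> str:
        return "LSODA" if self.method_hint == "stiff" else "RK45"


@dataclass
class Trajectory:
    """Solution paths on a fixed output grid.

    ``times`` in ms (strictly increasing), ``concentrations`` with shape
    (n_species, n_times) in uM, plus provenance metadata (network hash,
    solver options, drug name/dose).
    """

    times: np.ndarray
    concentrations: np.ndarray
    species_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, species: str) -> np.ndarray:
        try:
            i = self.species_names.index(species)
        except ValueError:
            raise KeyError(f"species {species!r} not in trajectory") from None
        return self.concentrations[i]

    def final_state(self) -> np.ndarray:
        return self.concentrations[:, -1].copy()

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format frame (time_ms, species, concentration_uM)."""
        n = len(self.times)
        return pd.DataFrame({
            "time_ms": np.repeat(self.times, len(self.species_names)),
            "species": np.tile(self.species_names, n),
            "concentration_uM": self.concentrations.T.ravel(),
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_output_grid(t_end: float, n_early: int = 150) -> np.ndarray:
    """Log-dense first hour, then hourly points out to ``t_end``."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    early_end = min(t_end, HOUR_MS)
    grid = [np.array([0.0]), np.geomspace(1e-2, early_end, n_early)]
    if t_end > HOUR_MS:
        grid.append(np.arange(HOUR_MS, t_end, HOUR_MS)[1:])
        grid.append(np.array([t_end]))
    times = np.unique(np.concatenate(grid))
    return times[times <= t_end]


def integrate(
    network: ReactionNetwork,
    initial_state: Sequence[float] | None = None,
    t_end: float = DAY_MS,
    options: SolverOptions | None = None,
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the network from ``initial_state`` (defaults to the
    network's initial concentrations) to ``t_end`` ms."""
    options = options or SolverOptions()
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    x0 = (network.initial_state() if initial_state is None
          else np.asarray(initial_state, dtype=float))
    if len(x0) != len(network.species):
        raise ValueError("initial_state does not match the species order")
    compiled = network.compiled()
    if t_eval is None:
        t_eval = default_output_grid(t_end)
    sol = solve_ivp(
        compiled.rhs, (0.0, float(t_end)), x0, method=options.method,
        t_eval=t_eval, rtol=options.rel_tol, atol=options.abs_tol,
        max_step=options.max_step,
    )
    if not sol.success:
        t_last = float(sol.t[-1]) if sol.t.size else 0.0
        x_last = sol.y[:, -1] if sol.t.size else x0
        raise IntegrationError(
            f"integration failed at t={t_last:.3g} ms: {sol.message}",
            t_last, x_last,
        )
    y = sol.y
    worst = y.min()
    if worst < -NEGATIVE_TOL:
        i = int(np.unravel_index(np.argmin(y), y.shape)[0])
        raise IntegrationError(
            f"concentration of {network.species_names[i]} went negative "
            f"({worst:.3e} uM) beyond tolerance", float(sol.t[-1]),
            y[:, -1],
        )
    y = np.clip(y, 0.0, None)
    return Trajectory(
        times=sol.t, concentrations=y, species_names=network.species_names,
        metadata={
            "network_hash": network.content_hash(),
            "solver": {"method": options.method, "rel_tol": options.rel_tol,
                       "abs_tol": options.abs_tol},
            "drug": None if network.drug is None else network.drug.name,
            "dose_uM": None if network.drug is None else network.drug.dose,
        },
    )


def _pool(traj: Trajectory, name: str) -> np.ndarray | None:
    return traj[name] if name in traj.species_names else None


def ac_on_fraction(traj: Trajectory) -> np.ndarray:
    """Fraction of activated AC: AC:alphaS_GTP over the total AC pool
    (free + stimulated + inhibited), elementwise along the trajectory."""
    on = _pool(traj, "AC:alphaS_GTP")
    free = _pool(traj, "AC")
    if on is None or free is None:
        raise KeyError("trajectory lacks the AC pools")
    inhibited = _pool(traj, "AC:alphaI_GTP")
    total = on + free + (inhibited if inhibited is not None else 0.0)
    if np.any(total <= 0):
        raise ValueError("total AC concentration is zero")
    return on / total


def receptor_occupancy(traj: Trajectory, receptor: str = "MOR") -> np.ndarray:
    """Percentage of receptors in the ligand-bound state."""
    bound_name = {"MOR": "MOR:OL", "5HTR4": "5HTR4:5HT"}.get(receptor)
    if bound_name is None:
        raise KeyError(f"unknown receptor {receptor!r}")
    free = traj[receptor]
    bound = traj[bound_name]
    total = free + bound
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = np.where(total > 0, 100.0 * bound / total, 0.0)
    return occ


def steady_state(
    network: ReactionNetwork,
    initial_state: Sequence[float] | None = None,
    tol: float = 1e-9,
    options: SolverOptions | None = None,
    max_horizon: float = 60 * DAY_MS,
    chunk: float = 12 * HOUR_MS,
) -> np.ndarray:
    """Drive the system to its fixed point by long-horizon integration.

    Convergence requires the relative change of every species over one
    simulated hour to drop below ``tol``.  Raises
    :class:`SteadyStateError` (naming the slowest species) if the horizon
    is exhausted, and refuses non-autonomous (pulsed) networks.
    """
    if network.pulse is not None:
        raise SteadyStateError("pulsed networks have no fixed point")
    options = options or SolverOptions()
    x = (network.initial_state() if initial_state is None
         else np.asarray(initial_state, dtype=float))
    compiled = network.compiled()
    floor = 1e3 * options.abs_tol
    t_done = 0.0
    while t_done < max_horizon:
        sol = solve_ivp(
            compiled.rhs, (0.0, chunk), x, method=options.method,
            rtol=options.rel_tol, atol=options.abs_tol,
            t_eval=np.array([chunk - HOUR_MS, chunk]),
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed during steady-state search: "
                f"{sol.message}", t_done, x,
            )
        prev, x = sol.y[:, 0], np.clip(sol.y[:, 1], 0.0, None)
        t_done += chunk
        rel = np.abs(x - prev) / np.maximum(np.abs(x), floor)
        if rel.max() < tol:
            return x
    slowest = network.species_names[int(np.argmax(rel))]
    raise SteadyStateError(
        f"no steady state within {max_horizon / DAY_MS:.1f} simulated days; "
        f"slowest species: {slowest} (relative change "
        f"{rel.max():.2e} per hour)"
    )


def conservation_drift(
    network: ReactionNetwork, traj: Trajectory
) -> dict[str, float]:
    """Maximum relative drift of each conserved moiety along a trajectory
    (diagnostic used by the property suite)."""
    out: dict[str, float] = {}
    ref = conserved_totals(network, traj.concentrations[:, 0])
    for name, total0 in ref.items():
        if total0 == 0:
            continue
        vals = np.array([
            conserved_totals(network, traj.concentrations[:, k])[name]
            for k in range(traj.concentrations.shape[1])
        ])
        out[name] = float(np.abs(vals - total0).max() / abs(total0))
    return out
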