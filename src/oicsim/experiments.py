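"""In-silico opioid-treatment experiments on the full network.

The headline experiment is an acute equianalgesic dose: the drug-free
system is pre-equilibrated, the dose is placed in the blood compartment
at t=0, and three readouts are extracted from the two-week trajectory:

* recovery time — first post-nadir return of the observable (activated
  AC, or cAMP) to 80% of its maximal observed level;
* depletion time — first time the tissue drug concentration falls below
  the drug's IC50 and stays there;
* peak receptor occupancy — maximum percentage of MOR bound.

A degradation-rate sweep repeats the cAMP recovery measurement over a
(Kd x dose) grid for several tissue degradation rates kdegOL, fixing
koff and deriving kon = koff/Kd per cell, and reports the 2-day
iso-recovery contour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .engine import (
    DAY_MS, HOUR_MS, SolverOptions, Trajectory, ac_on_fraction,
    integrate, receptor_occupancy, default_output_grid,
)
from .network import (
    ConfigurationError, DrugSpec, RateTable, ReactionNetwork, build_network,
)

__all__ = [
    "TreatmentScenario", "RecoveryReport", "SweepResult",
    "run_acute_treatment", "recovery_time", "depletion_time",
    "degradation_sweep", "pathway_independence_check",
    "drug_free_equilibrium",
]

#: default recovery threshold: 80% of the maximal observed level
DEFAULT_THRESHOLD = 0.8


@dataclass(frozen=True)
class TreatmentScenario:
    """One acute-treatment protocol: drug, dose (defaults to the drug's
    equianalgesic dose), drug-free pre-equilibration and observation
    horizon (ms)."""

    drug: DrugSpec
    dose: float | None = None
    pre_equilibration: float = 24 * HOUR_MS
    horizon: float = 14 * DAY_MS
    serotonin_drive: Literal["continuous", "pulsed"] = "continuous"

    def __post_init__(self) -> None:
        if self.pre_equilibration < 0:
            raise ConfigurationError("pre_equilibration must be >= 0")
        if self.horizon <= 0:
            raise ConfigurationError("horizon must be positive")

    @property
    def applied_dose(self) -> float:
        return self.drug.dose if self.dose is None else self.dose


@dataclass
class RecoveryReport:
    """Readouts of one treatment scenario.  Times are in hours; a
    censored recovery (no crossing within the horizon) is reported as
    the horizon with ``censored=True``."""

    recovery_time: float
    depletion_time_to_ic50: float | None
    peak_occupancy: float
    threshold_fraction: float = DEFAULT_THRESHOLD
    censored: bool = False


@dataclass
class SweepResult:
    """Recovery-time matrix (hours) over a Kd x dose grid at one
    degradation rate; ``contour_2day`` holds per-Kd interpolated doses at
    which recovery crosses two days (NaN where it never does)."""

    kdeg: float
    kd_grid: np.ndarray
    dose_grid: np.ndarray
    recovery_matrix: np.ndarray
    censored: np.ndarray
    contour_2day: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.recovery_matrix = np.asarray(self.recovery_matrix, dtype=float)
        if self.recovery_matrix.shape != (len(self.kd_grid), len(self.dose_grid)):
            raise ValueError("matrix shape must be |kd_grid| x |dose_grid|")


def _full_network(drug: DrugSpec, rates: RateTable | None,
                  pulse=None) -> ReactionNetwork:
    return build_network(rates or RateTable(), drug=drug, pulse=pulse)


def drug_free_equilibrium(
    rates: RateTable | None = None,
    pre_equilibration: float = 24 * HOUR_MS,
    options: SolverOptions | None = None,
    drug: DrugSpec | None = None,
) -> np.ndarray:
    """State of the full network after drug-free pre-equilibration.

    With no ligand anywhere the opioid arm is inert, so the state does
    not depend on which drug parameterises it; any spec works as a
    placeholder."""
    drug = drug or DrugSpec("placebo", Kd=1.0)
    net = _full_network(drug, rates)
    traj = integrate(net, t_end=pre_equilibration, options=options)
    return traj.final_state()


def run_acute_treatment(
    scenario: TreatmentScenario,
    rates: RateTable | None = None,
    options: SolverOptions | None = None,
    ic50: float | None = None,
    observable: Literal["ac_on", "camp"] = "ac_on",
    baseline_state: np.ndarray | None = None,
) -> tuple[Trajectory, RecoveryReport]:
    """Simulate one acute dose and extract the recovery readouts.

    The drug-free system is pre-equilibrated (unless ``baseline_state``
    is supplied), the dose is added to the blood compartment (or tissue,
    per the drug spec) at t=0, and the combined network is integrated
    over the scenario horizon.  ``ic50`` (uM) enables the
    depletion-to-IC50 readout.
    """
    from .network import PulseTrain
    pulse = PulseTrain() if scenario.serotonin_drive == "pulsed" else None
    net = _full_network(scenario.drug, rates, pulse=pulse)
    if baseline_state is None:
        baseline_state = drug_free_equilibrium(
            rates, scenario.pre_equilibration, options, drug=scenario.drug
        )
    x0 = np.asarray(baseline_state, dtype=float).copy()
    dose_species = ("OL_Blood" if scenario.drug.dose_compartment == "blood"
                    else "OL")
    x0[net.species_index(dose_species)] += scenario.applied_dose

    traj = integrate(net, initial_state=x0, t_end=scenario.horizon,
                     options=options)
    baseline_value = _observable_of_state(net, baseline_state, observable)
    rec, censored = recovery_time(
        traj, observable=observable, threshold_fraction=DEFAULT_THRESHOLD,
        baseline=baseline_value,
    )
    dep = None
    if ic50 is not None:
        dep = depletion_time(traj, scenario.drug, ic50)
    peak_occ = float(receptor_occupancy(traj, "MOR").max())
    report = RecoveryReport(
        recovery_time=rec, depletion_time_to_ic50=dep,
        peak_occupancy=peak_occ, censored=censored,
    )
    return traj, report


def _observable_path(traj: Trajectory, observable: str) -> np.ndarray:
    if observable == "ac_on":
        return ac_on_fraction(traj)
    if observable == "camp":
        return traj["cAMP"]
    raise ValueError(f"unknown observable {observable!r}")


def _observable_of_state(net: ReactionNetwork, state: np.ndarray,
                         observable: str) -> float:
    names = net.species_names
    if observable == "ac_on":
        on = state[names.index("AC:alphaS_GTP")]
        total = on + state[names.index("AC")] + state[names.index("AC:alphaI_GTP")]
        return float(on / total) if total > 0 else 0.0
    return float(state[names.index("cAMP")])


def recovery_time(
    traj: Trajectory,
    observable: Literal["ac_on", "camp"] = "ac_on",
    threshold_fraction: float = DEFAULT_THRESHOLD,
    baseline: float | None = None,
) -> tuple[float, bool]:
    """First post-nadir crossing of threshold x (maximal observed value).

    The maximum is taken over the whole trajectory and, if given, the
    pre-dose ``baseline`` level.  Linear interpolation between grid
    points; returns (hours, censored) where a censored result means the
    observable never crossed within the horizon.
    """
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    y = _observable_path(traj, observable)
    t = traj.times
    y_max = float(y.max()) if baseline is None else max(float(y.max()), baseline)
    if y_max <= 0:
        return 0.0, False
    thresh = threshold_fraction * y_max
    i_min = int(np.argmin(y))
    if y[i_min] >= thresh:
        return 0.0, False
    above = np.nonzero(y[i_min:] >= thresh)[0]
    if above.size == 0:
        return float(t[-1] / HOUR_MS), True
    j = i_min + above[0]
    # linear interpolation inside the bracketing interval
    t_cross = t[j] if j == 0 else (
        t[j - 1] + (thresh - y[j - 1]) * (t[j] - t[j - 1]) / (y[j] - y[j - 1])
    )
    return float(t_cross / HOUR_MS), False


def depletion_time(
    traj: Trajectory, drug: DrugSpec, ic50: float
) -> float:
    """First time (hours) the tissue drug concentration falls below
    ``ic50`` (uM) and stays below for the rest of the trajectory."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    ol = traj["OL"]
    t = traj.times
    below = ol < ic50
    if below.all():
        return 0.0
    if not below[-1]:
        return float(t[-1] / HOUR_MS)  # censored at horizon
    # last index that is at or above ic50
    j = int(np.nonzero(~below)[0][-1])
    if j + 1 >= len(t):
        return float(t[-1] / HOUR_MS)
    t_cross = t[j] + (ol[j] - ic50) * (t[j + 1] - t[j]) / (ol[j] - ol[j + 1])
    return float(t_cross / HOUR_MS)


def degradation_sweep(
    kdeg_values: Sequence[float],
    kd_grid: Sequence[float] | None = None,
    dose_grid: Sequence[float] | None = None,
    fixed_koff: float = 5e-5,
    rates: RateTable | None = None,
    options: SolverOptions | None = None,
    horizon: float = 14 * DAY_MS,
    observable: Literal["ac_on", "camp"] = "camp",
) -> list[SweepResult]:
    """cAMP recovery times over (Kd, dose) grids for each kdegOL.

    koff is fixed and kon = koff/Kd per cell.  The drug-free equilibrium
    is computed once and shared by all cells (the opioid arm is inert
    without ligand).  Individual cell failures are recorded as NaN and
    the sweep continues.
    """
    kd_grid = np.asarray(
        kd_grid if kd_grid is not None else np.geomspace(0.1, 1000.0, 12)
    )
    dose_grid = np.asarray(
        dose_grid if dose_grid is not None else np.geomspace(1e-3, 1e2, 12)
    )
    baseline = drug_free_equilibrium(rates, options=options)
    results: list[SweepResult] = []
    for kdeg in kdeg_values:
        matrix = np.full((len(kd_grid), len(dose_grid)), np.nan)
        censored = np.zeros_like(matrix, dtype=bool)
        for i, kd in enumerate(kd_grid):
            for j, dose in enumerate(dose_grid):
                drug = DrugSpec("sweep", Kd=float(kd), koff=fixed_koff,
                                kdegOL=float(kdeg), dose=float(dose))
                scenario = TreatmentScenario(drug, horizon=horizon)
                try:
                    _, report = run_acute_treatment(
                        scenario, rates=rates, options=options,
                        observable=observable, baseline_state=baseline,
                    )
                    matrix[i, j] = report.recovery_time
                    censored[i, j] = report.censored
                except Exception:
                    matrix[i, j] = np.nan
        results.append(SweepResult(
            kdeg=float(kdeg), kd_grid=kd_grid, dose_grid=dose_grid,
            recovery_matrix=matrix, censored=censored,
            contour_2day=_iso_contour(kd_grid, dose_grid, matrix, 48.0),
        ))
    return results


def _iso_contour(kd_grid: np.ndarray, dose_grid: np.ndarray,
                 matrix: np.ndarray, level_hours: float) -> np.ndarray:
    """Per-Kd dose at which recovery time crosses ``level_hours``,
    interpolated in log-dose (NaN where the row never crosses)."""
    out = np.full(len(kd_grid), np.nan)
    logd = np.log10(dose_grid)
    for i, row in enumerate(matrix):
        ok = np.isfinite(row)
        if ok.sum() < 2:
            continue
        r, ld = row[ok], logd[ok]
        crossings = np.nonzero(np.diff(np.sign(r - level_hours)))[0]
        if crossings.size == 0:
            continue
        k = crossings[0]
        frac = (level_hours - r[k]) / (r[k + 1] - r[k])
        out[i] = 10 ** (ld[k] + frac * (ld[k + 1] - ld[k]))
    return out


def pathway_independence_check(
    scenario: TreatmentScenario,
    rates: RateTable | None = None,
    options: SolverOptions | None = None,
    tol: float = 1e-6,
) -> dict:
    """Compare the serotonergic paths with and without the opioid dose.

    Runs the dosed and drug-free scenarios from the same pre-equilibrated
    state on the same output grid and reports the maximum relative
    difference of the 5HT and 5HTR4:5HT paths; the pathways upstream of
    AC are structurally uncoupled, so the difference should vanish to
    integration tolerance.
    """
    baseline = drug_free_equilibrium(
        rates, scenario.pre_equilibration, options, drug=scenario.drug
    )
    net = _full_network(scenario.drug, rates)
    grid = default_output_grid(scenario.horizon)
    x_dosed = baseline.copy()
    dose_species = ("OL_Blood" if scenario.drug.dose_compartment == "blood"
                    else "OL")
    x_dosed[net.species_index(dose_species)] += scenario.applied_dose
    traj_dosed = integrate(net, x_dosed, scenario.horizon, options, t_eval=grid)
    traj_free = integrate(net, baseline, scenario.horizon, options, t_eval=grid)
    diffs = compare_paths(traj_dosed, traj_free, ("5HT", "5HTR4:5HT"))
    worst = max(diffs.values())
    return {"max_relative_difference": worst, "per_species": diffs,
            "passed": worst < tol, "tolerance": tol}


def compare_paths(
    traj_a: Trajectory, traj_b: Trajectory, species: Sequence[str]
) -> dict[str, float]:
    """Maximum relative difference of the named species paths between two
    trajectories on the same output grid."""
    if traj_a.times.shape != traj_b.times.shape or not np.allclose(
            traj_a.times, traj_b.times):
        raise ValueError("trajectories must share the same output grid")
    diffs: dict[str, float] = {}
    for sp in species:
        a, b = traj_a[sp], traj_b[sp]
        scale = np.maximum(np.abs(b), np.abs(b).max() * 1e-6 + 1e-30)
        diffs[sp] = float(np.max(np.abs(a - b) / scale))
    return diffs
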