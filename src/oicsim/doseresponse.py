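"""Dose-response simulation and four-parameter logistic (4PL) fitting.

Two in-silico assays are provided:

* an agonist assay: a bolus of serotonin is applied to the serotonergic
  arm (endogenous synthesis/release silenced so that the bolus is the
  only drive) and the quasi-steady activated-AC fraction is read out;
* an inhibition assay mimicking a forskolin experiment: every AC molecule
  starts in the stimulated complex, the opioid is clamped at a constant
  bath concentration, and cAMP is read out after a fixed incubation
  interval, normalised to the drug-free control.

Curves are fitted with a 4PL (Hill) model in log10-dose space; the
midpoint is the EC50 (rising curves) or IC50 (falling curves) and pIC50
is -log10(IC50 in molar).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import lmfit

from .calibration import CampParams, steady_state_camp
from .engine import (
    HOUR_MS, SolverOptions, Trajectory, ac_on_fraction, integrate,
)
from .network import (
    ConfigurationError, DrugSpec, RateTable, ReactionNetwork, build_network,
    default_drugs,
)

__all__ = [
    "DoseGrid", "HillFit", "FitQualityError", "agonist_network",
    "inhibition_network", "simulate_agonist_curve",
    "simulate_inhibition_curve", "fit_hill", "pic50",
    "receptor_density_sweep", "agonist_ac_on_model",
]

#: default incubation interval of the inhibition assay (30 min in ms)
DEFAULT_READOUT_MS = 30 * 60 * 1e3
#: observation window of the agonist assay (the activated-AC plateau is
#: reached within minutes; receptor-bound serotonin decays over hours)
AGONIST_WINDOW_MS = 4 * HOUR_MS


class FitQualityError(RuntimeError):
    """Raised when dose-response data are not usably sigmoidal."""


@dataclass(frozen=True)
class DoseGrid:
    """Strictly increasing, positive, log-spaced doses in uM."""

    doses: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        if d.ndim != 1 or len(d) < 2:
            raise ValueError("need at least two doses")
        if (d <= 0).any() or (np.diff(d) <= 0).any():
            raise ValueError("doses must be positive and strictly increasing")
        object.__setattr__(self, "doses", d)

    @classmethod
    def log_spaced(cls, low: float, high: float, n_points: int = 24) -> "DoseGrid":
        return cls(np.geomspace(low, high, n_points))

    @classmethod
    def centered_on(cls, center: float, span_decades: float = 6.0,
                    n_points: int = 24) -> "DoseGrid":
        half = 10 ** (span_decades / 2)
        return cls.log_spaced(center / half, center * half, n_points)

    def __len__(self) -> int:
        return len(self.doses)


@dataclass
class HillFit:
    """Fitted 4PL: ``bottom``/``top`` are the low/high asymptote values,
    ``midpoint`` (uM) the half-way dose, ``hill_slope`` the positive Hill
    coefficient; ``direction`` records whether the response rises or
    falls with dose."""

    bottom: float
    top: float
    midpoint: float
    hill_slope: float
    direction: str
    residual_norm: float
    standard_errors: dict = field(default_factory=dict)

    @property
    def ec50(self) -> float:
        return self.midpoint

    @property
    def ic50(self) -> float:
        if self.direction != "fall":
            raise ValueError("IC50 is defined for inhibition fits")
        return self.midpoint

    def predict(self, doses: Sequence[float]) -> np.ndarray:
        x = np.asarray(doses, dtype=float)
        frac = x ** self.hill_slope / (
            self.midpoint ** self.hill_slope + x ** self.hill_slope
        )
        lo, hi = ((self.bottom, self.top) if self.direction == "rise"
                  else (self.top, self.bottom))
        return lo + (hi - lo) * frac


# --- assay networks ---------------------------------------------------------

def agonist_network(
    rates: RateTable | None = None,
    receptor_density: float = 5e-6,
    dose: float = 0.0,
) -> ReactionNetwork:
    """Serotonin-arm network prepared for one agonist bolus.

    Endogenous synthesis and release are silenced so the applied bolus is
    the only serotonergic drive; the bolus is placed in the extracellular
    5HT pool at t=0.
    """
    rates = (rates or RateTable()).with_overrides(
        ksynthesis5HTIN=0.0, krelease5HTIN=0.0
    )
    net = build_network(rates, drug=None, pathways=("serotonin",))
    return net.with_initial(**{
        "5HT": dose, "5HT_IN": 0.0, "5HTR4": receptor_density,
    })


def inhibition_network(
    drug: DrugSpec,
    dose: float,
    rates: RateTable | None = None,
    ac_total: float = 2e-3,
) -> ReactionNetwork:
    """Full network prepared for the forskolin-type inhibition assay.

    All AC starts in the stimulated complex ``AC:alphaS_GTP`` (the
    G-alphaS it carries comes on top of the resting heterotrimer pool, so
    conservation is book-kept consistently); the serotonergic drive is
    silenced; the opioid is clamped at the bath concentration ``dose`` in
    the tissue compartment.
    """
    rates = (rates or RateTable()).with_overrides(
        ksynthesis5HTIN=0.0, krelease5HTIN=0.0
    )
    net = build_network(rates, drug=drug)
    net = net.with_initial(**{
        "5HT": 0.0, "5HT_IN": 0.0,
        "AC": 0.0, "AC:alphaS_GTP": ac_total,
        "OL": dose, "OL_Blood": 0.0,
    })
    return net.with_clamped("OL")


def simulate_agonist_curve(
    network_factory: Callable[[float], ReactionNetwork] | None = None,
    doses: DoseGrid | None = None,
    readout: Literal["ac_on_steady", "camp_steady"] = "ac_on_steady",
    rates: RateTable | None = None,
    receptor_density: float = 5e-6,
    options: SolverOptions | None = None,
    window_ms: float = AGONIST_WINDOW_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-steady response versus serotonin bolus dose.

    For each dose the serotonin arm is integrated over ``window_ms`` and
    the plateau (maximum) activated-AC fraction is recorded;
    ``camp_steady`` maps that fraction through the steady-state cAMP
    law."""
    doses = doses or DoseGrid.log_spaced(1e-3, 1e2, 24)
    if network_factory is None:
        network_factory = lambda d: agonist_network(rates, receptor_density, d)
    responses = np.empty(len(doses))
    for k, dose in enumerate(doses.doses):
        net = network_factory(dose)
        traj = integrate(net, t_end=window_ms, options=options)
        responses[k] = float(ac_on_fraction(traj).max())
    if readout == "camp_steady":
        r = rates or RateTable()
        params = CampParams(r.k1, r.k2, r.EC50_hill, r.n_hill)
        responses = steady_state_camp(responses, params)
    elif readout != "ac_on_steady":
        raise ValueError(f"unknown readout {readout!r}")
    return doses.doses.copy(), responses


def agonist_ac_on_model(
    rates: RateTable | None = None,
    options: SolverOptions | None = None,
) -> Callable[[float, float], float]:
    """Map (serotonin bolus uM, receptor density uM) -> quasi-steady
    activated-AC fraction, backed by the agonist assay simulation.
    Used as the mechanistic input of the cAMP calibration."""

    def model(serotonin: float, density: float) -> float:
        if serotonin == 0:
            return 0.0
        net = agonist_network(rates, density, serotonin)
        traj = integrate(net, t_end=AGONIST_WINDOW_MS, options=options)
        return float(ac_on_fraction(traj).max())

    return model


def simulate_inhibition_curve(
    network_factory: Callable[[float], ReactionNetwork] | None = None,
    drug: DrugSpec | None = None,
    doses: DoseGrid | None = None,
    readout_time: float = DEFAULT_READOUT_MS,
    rates: RateTable | None = None,
    options: SolverOptions | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """cAMP remaining after the incubation interval versus clamped opioid
    dose, as a percentage of the drug-free control."""
    if drug is None and network_factory is None:
        raise ConfigurationError("either a drug or a network factory is required")
    if doses is None:
        center = drug.kd_uM if drug is not None else 1e-2
        doses = DoseGrid.centered_on(center)
    if network_factory is None:
        network_factory = lambda d: inhibition_network(drug, d, rates)

    def camp_at_readout(dose: float) -> float:
        net = network_factory(dose)
        traj = integrate(net, t_end=readout_time, options=options)
        return float(traj["cAMP"][-1])

    control = camp_at_readout(0.0)
    if control <= 0:
        raise FitQualityError("drug-free control produced no cAMP")
    responses = np.array([camp_at_readout(d) for d in doses.doses])
    return doses.doses.copy(), 100.0 * responses / control


# --- fitting ----------------------------------------------------------------

def _sigmoidal_or_raise(doses: np.ndarray, responses: np.ndarray,
                        direction: str) -> None:
    """Cheap monotonicity screen: the rank correlation between dose and
    response must carry the expected sign well beyond noise."""
    from scipy.stats import spearmanr
    rho = spearmanr(doses, responses).statistic
    expected = 1.0 if direction == "rise" else -1.0
    if not np.isfinite(rho) or rho * expected < 0.6:
        raise FitQualityError(
            f"data are not {direction!r}-sigmoidal "
            f"(rank correlation {rho:.2f})"
        )


def fit_hill(
    doses: Sequence[float],
    responses: Sequence[float],
    direction: Literal["rise", "fall"] = "rise",
) -> HillFit:
    """Least-squares 4PL fit in log10-dose space.

    The slope sign is fixed by ``direction`` for conditioning; the
    midpoint is the EC50 (rise) or IC50 (fall).  Requires at least five
    points bracketing the midpoint.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("doses and responses must be 1-D and equal length")
    if len(x) < 5:
        raise ValueError("need at least five dose points")
    if (x <= 0).any():
        raise ValueError("doses must be positive")
    _sigmoidal_or_raise(x, y, direction)

    logx = np.log10(x)
    norm = (y - y.min()) / max(np.ptp(y), 1e-30)
    mid_guess = float(np.interp(0.5, norm, logx) if direction == "rise"
                      else np.interp(0.5, norm[::-1], logx[::-1]))

    params = lmfit.Parameters()
    params.add("left", value=float(y[0]))          # low-dose asymptote
    params.add("right", value=float(y[-1]))        # high-dose asymptote
    params.add("logmid", value=mid_guess, min=logx[0] - 3, max=logx[-1] + 3)
    params.add("slope", value=1.0, min=1e-3, max=20.0)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        frac = 1.0 / (1.0 + 10 ** (p["slope"] * (p["logmid"] - logx)))
        model = p["left"] + (p["right"] - p["left"]) * frac
        return model - y

    out = lmfit.minimize(residual, params, method="leastsq")
    p = out.params
    left, right = float(p["left"]), float(p["right"])
    if direction == "rise" and right < left or direction == "fall" and right > left:
        # asymptotes came out inverted relative to the requested direction
        raise FitQualityError(
            f"fit asymptotes contradict direction {direction!r}"
        )
    errs = {name: (p[name].stderr if p[name].stderr is not None else math.nan)
            for name in p}
    mid = 10 ** float(p["logmid"])
    mid_err = (math.log(10) * mid * errs["logmid"]
               if math.isfinite(errs["logmid"]) else math.nan)
    return HillFit(
        bottom=min(left, right), top=max(left, right), midpoint=mid,
        hill_slope=float(p["slope"]), direction=direction,
        residual_norm=float(np.linalg.norm(out.residual)),
        standard_errors={
            "bottom": errs["left"] if left <= right else errs["right"],
            "top": errs["right"] if left <= right else errs["left"],
            "midpoint": mid_err,
            "hill_slope": errs["slope"],
        },
    )


def pic50(fit: HillFit) -> float:
    """-log10(IC50 in molar); the fit midpoint is in uM."""
    return 6.0 - math.log10(fit.ic50)


def receptor_density_sweep(
    densities: Sequence[float],
    doses: DoseGrid | None = None,
    rates: RateTable | None = None,
    readout: str = "ac_on_steady",
    options: SolverOptions | None = None,
) -> dict:
    """Agonist curves and Hill fits across 5HTR4 densities.

    Returns per-density fits plus an EC50 mean/sd and the Emax window;
    individual fit failures are recorded and the sweep continues.
    """
    densities = np.asarray(densities, dtype=float)
    if (densities <= 0).any():
        raise ValueError("densities must be positive")
    fits: list[HillFit | None] = []
    errors: dict[float, str] = {}
    emax: list[float] = []
    for density in densities:
        d, r = simulate_agonist_curve(
            doses=doses, readout=readout, rates=rates,
            receptor_density=float(density), options=options,
        )
        emax.append(float(r.max()))
        try:
            fits.append(fit_hill(d, r, direction="rise"))
        except (FitQualityError, ValueError) as exc:
            fits.append(None)
            errors[float(density)] = str(exc)
    ec50s = np.array([f.midpoint for f in fits if f is not None])
    slopes = np.array([f.hill_slope for f in fits if f is not None])
    return {
        "densities": densities,
        "fits": fits,
        "errors": errors,
        "ec50_mean": float(ec50s.mean()) if ec50s.size else math.nan,
        "ec50_sd": float(ec50s.std(ddof=1)) if ec50s.size > 1 else math.nan,
        "slope_mean": float(slopes.mean()) if slopes.size else math.nan,
        "emax_window": (min(emax), max(emax)),
        "emax": np.array(emax),
    }
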