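"""Reaction network for coupled serotonin / mu-opioid signalling.

The model couples two GPCR pathways that converge on adenylyl cyclase (AC):

* a serotonergic arm (reactions S1-S12): serotonin (5HT) is synthesised in
  enterochromaffin cells (species ``5HT_IN``), released, degraded and taken
  back up; extracellular 5HT binds the Gs-coupled receptor 5HTR4, whose
  ligand-bound form catalyses Gs activation; GTP-bound alphaS associates
  with AC to form the active complex ``AC:alphaS_GTP``;
* an opioid arm (O1-O10): an opioid ligand (OL) enters the blood
  compartment, transfers to tissue, degrades, binds the Gi-coupled
  mu-opioid receptor MOR and drives alphaI activation; GTP-bound alphaI
  sequesters AC into the inhibited complex ``AC:alphaI_GTP``;
* a competing block (C1-C3): cAMP is produced through a Hill function of
  the activated AC fraction and degraded first order; activated alphaI can
  additionally displace AC out of the stimulatory complex.

All propensities follow mass action except C1 (Hill production).
Concentrations are in uM and time in ms throughout; reporting layers
convert to hours/days.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ConfigurationError", "SpeciesDef", "ReactionDef", "RateTable",
    "DrugSpec", "PulseTrain", "ReactionNetwork", "build_network",
    "stoichiometric_matrix", "propensities", "conserved_totals",
    "default_drugs", "default_initial_concentrations", "MOIETIES",
    "PATHWAYS",
]

PATHWAYS = ("serotonin", "opioid", "competing")


class ConfigurationError(ValueError):
    """Raised for inconsistent network / configuration requests."""


@dataclass(frozen=True)
class SpeciesDef:
    """One chemical species: name, initial concentration (uM), pathway tag."""

    name: str
    initial_concentration: float
    pathway_tag: str  # serotonin | opioid | shared | messenger

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise ConfigurationError(
                f"initial concentration of {self.name} must be >= 0"
            )


@dataclass(frozen=True)
class ReactionDef:
    """One reaction: reactant/product multisets and the rate-law kind.

    ``rate_law`` is ``mass_action`` for every reaction except C1
    (``hill_production``); a first-order decay is simply mass action with
    one reactant.  ``rate_constant_name`` refers to a :class:`RateTable`
    field, or to the per-drug constants ``kbindOL``/``kunbindOL``/
    ``kdegOL`` resolved from the network's :class:`DrugSpec`.
    """

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_law: str = "mass_action"
    rate_constant_name: str = ""


# --- rate constants ---------------------------------------------------------

@dataclass(frozen=True)
class RateTable:
    """Named rate constants of the model (ms^-1, or uM^-1 ms^-1 for
    bimolecular steps; ``ksynthesis5HTIN`` is a zeroth-order flux in
    uM ms^-1).

    ``k1``/``k2``/``EC50_hill``/``n_hill`` parameterise the Hill-type cAMP
    production/degradation pair (reactions C1/C2).  ``k3`` governs the
    displacement of AC from the stimulatory complex by activated alphaI;
    it defaults to the AC association rate since it is the same class of
    molecular event (a GTP-bound G-alpha engaging AC).
    """

    ksynthesis5HTIN: float = 0.05
    krelease5HTIN: float = 0.001
    kdegrade5HTIN: float = 0.01
    kdegrade5HT: float = 0.01
    kreuptake5HT: float = 2.38e-8
    kbind5HT: float = 4.46e-3
    kunbind5HT: float = 5e-8
    ktransfer: float = 1.38e-7
    kelimination: float = 1e-8
    kactivation: float = 0.2
    kassembly: float = 0.033
    khydrolization: float = 6.7e-5
    kACassociation_s: float = 3.5e-3
    kACassociation_i: float = 3.5e-3
    kACdissociation_s: float = 3.3e-6
    kACdissociation_i: float = 3.3e-6
    k3: float = 3.5e-3
    k1: float = 6.1e-3
    k2: float = 141.3
    EC50_hill: float = 135.0
    n_hill: float = 2.44

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ConfigurationError(f"rate constant {name} must be >= 0")
        if self.n_hill <= 0 or self.EC50_hill <= 0:
            raise ConfigurationError("Hill parameters must be positive")

    def with_overrides(self, **overrides: float) -> "RateTable":
        unknown = set(overrides) - set(self.__dict__)
        if unknown:
            raise ConfigurationError(
                f"unknown rate constant(s): {sorted(unknown)}"
            )
        return replace(self, **overrides)


@dataclass(frozen=True)
class DrugSpec:
    """A mu-opioid ligand.

    ``Kd`` is in nM; ``koff`` (ms^-1) is shared across drugs by default
    and ``kon`` (uM^-1 ms^-1) follows from kon = koff / Kd after nM->uM
    conversion.  ``kdegOL`` is the tissue degradation rate; pharmaceutical
    opioids default to 1e-8 ms^-1, Endomorphin-2 to 1.02e-4 ms^-1.
    ``dose`` is the acute equianalgesic dose in uM, administered into
    ``dose_compartment`` ("blood" by default).
    ``degrade_in_blood`` optionally applies ``kdegOL`` to the blood
    compartment as well (off by default).
    """

    name: str
    Kd: float                      # nM
    koff: float = 5e-5             # ms^-1
    kon: float | None = None       # uM^-1 ms^-1; derived if omitted
    kdegOL: float = 1e-8           # ms^-1
    dose: float = 0.0              # uM
    dose_compartment: str = "blood"
    degrade_in_blood: bool = False

    def __post_init__(self) -> None:
        if self.Kd <= 0 or self.koff <= 0 or self.kdegOL < 0:
            raise ConfigurationError("drug kinetic constants must be positive")
        if self.dose < 0:
            raise ConfigurationError("dose must be >= 0")
        if self.dose_compartment not in ("blood", "tissue"):
            raise ConfigurationError(
                f"unknown dose compartment {self.dose_compartment!r}"
            )
        if self.kon is None:
            object.__setattr__(self, "kon", self.koff / self.kd_uM)
        elif not math.isclose(self.kon * self.kd_uM, self.koff, rel_tol=1e-6):
            raise ConfigurationError(
                f"{self.name}: kon must equal koff/Kd "
                f"(got kon={self.kon}, koff/Kd={self.koff / self.kd_uM})"
            )

    @property
    def kd_uM(self) -> float:
        return self.Kd * 1e-3


def default_drugs() -> dict[str, DrugSpec]:
    """The four reference ligands with literature affinities and
    equianalgesic acute doses (10 mg, 1 mg, 0.1 mg and the endogenous
    equivalent)."""
    return {
        "Morphine": DrugSpec("Morphine", Kd=76.08, dose=4.7),
        "Methadone": DrugSpec("Methadone", Kd=41.92, dose=0.2),
        "Fentanyl": DrugSpec("Fentanyl", Kd=0.57, dose=0.01),
        "Endomorphin-2": DrugSpec(
            "Endomorphin-2", Kd=2.33, kdegOL=1.02e-4, dose=1425.51
        ),
    }


# --- species / initial conditions ------------------------------------------

# AC initial: the source table prints an implausible 2e-34; the package
# default is 2e-3 uM (configurable).
_SEROTONIN_SPECIES = (
    ("5HT_IN", 1.8e-4, "serotonin"),
    ("5HT", 1e-7, "serotonin"),
    ("5HTR4", 5e-6, "serotonin"),
    ("5HTR4:5HT", 0.0, "serotonin"),
    ("alphaS_GDP:bgS", 0.05, "serotonin"),
    ("alphaS_GTP", 0.0, "serotonin"),
    ("alphaS_GDP", 0.0, "serotonin"),
    ("bgS", 0.0, "serotonin"),
    ("AC", 2e-3, "shared"),
    ("AC:alphaS_GTP", 0.0, "serotonin"),
)
_OPIOID_SPECIES = (
    ("OL_Blood", 0.0, "opioid"),
    ("OL", 0.0, "opioid"),
    ("MOR", 5e-6, "opioid"),
    ("MOR:OL", 0.0, "opioid"),
    ("alphaI_GDP:bgI", 0.05, "opioid"),
    ("alphaI_GTP", 0.0, "opioid"),
    ("alphaI_GDP", 0.0, "opioid"),
    ("bgI", 0.0, "opioid"),
    ("AC", 2e-3, "shared"),
    ("AC:alphaI_GTP", 0.0, "opioid"),
)
_CAMP_SPECIES = (("cAMP", 0.0, "messenger"),)


def default_initial_concentrations() -> dict[str, float]:
    out: dict[str, float] = {}
    for name, x0, _ in _SEROTONIN_SPECIES + _OPIOID_SPECIES + _CAMP_SPECIES:
        out[name] = x0
    return out


_SEROTONIN_REACTIONS = (
    ReactionDef("S1", (), ("5HT_IN",), "mass_action", "ksynthesis5HTIN"),
    ReactionDef("S2", ("5HT_IN",), ("5HT",), "mass_action", "krelease5HTIN"),
    ReactionDef("S3", ("5HT_IN",), (), "mass_action", "kdegrade5HTIN"),
    ReactionDef("S4", ("5HT",), (), "mass_action", "kdegrade5HT"),
    ReactionDef("S5", ("5HT",), ("5HT_IN",), "mass_action", "kreuptake5HT"),
    ReactionDef("S6", ("5HT", "5HTR4"), ("5HTR4:5HT",), "mass_action",
                "kbind5HT"),
    ReactionDef("S7", ("5HTR4:5HT",), ("5HTR4",), "mass_action",
                "kunbind5HT"),
    ReactionDef("S8", ("5HTR4:5HT", "alphaS_GDP:bgS"),
                ("5HTR4:5HT", "alphaS_GTP", "bgS"), "mass_action",
                "kactivation"),
    ReactionDef("S9", ("alphaS_GTP",), ("alphaS_GDP",), "mass_action",
                "khydrolization"),
    ReactionDef("S10", ("alphaS_GDP", "bgS"), ("alphaS_GDP:bgS",),
                "mass_action", "kassembly"),
    ReactionDef("S11", ("alphaS_GTP", "AC"), ("AC:alphaS_GTP",),
                "mass_action", "kACassociation_s"),
    ReactionDef("S12", ("AC:alphaS_GTP",), ("alphaS_GTP", "AC"),
                "mass_action", "kACdissociation_s"),
)
_OPIOID_REACTIONS = (
    ReactionDef("O1", ("OL", "MOR"), ("MOR:OL",), "mass_action", "kbindOL"),
    ReactionDef("O2", ("MOR:OL",), ("MOR",), "mass_action", "kunbindOL"),
    ReactionDef("O3", ("OL_Blood",), ("OL",), "mass_action", "ktransfer"),
    ReactionDef("O4", ("OL_Blood",), (), "mass_action", "kelimination"),
    ReactionDef("O5", ("OL",), (), "mass_action", "kdegOL"),
    ReactionDef("O6", ("MOR:OL", "alphaI_GDP:bgI"),
                ("MOR:OL", "alphaI_GTP", "bgI"), "mass_action",
                "kactivation"),
    ReactionDef("O7", ("alphaI_GTP",), ("alphaI_GDP",), "mass_action",
                "khydrolization"),
    ReactionDef("O8", ("alphaI_GDP", "bgI"), ("alphaI_GDP:bgI",),
                "mass_action", "kassembly"),
    ReactionDef("O9", ("alphaI_GTP", "AC"), ("AC:alphaI_GTP",),
                "mass_action", "kACassociation_i"),
    ReactionDef("O10", ("AC:alphaI_GTP",), ("alphaI_GTP", "AC"),
                "mass_action", "kACdissociation_i"),
)
_COMPETING_REACTIONS = (
    ReactionDef("C1", (), ("cAMP",), "hill_production", "k2"),
    ReactionDef("C2", ("cAMP",), (), "mass_action", "k1"),
    ReactionDef("C3", ("alphaI_GTP", "AC:alphaS_GTP"),
                ("AC:alphaI_GTP", "alphaS_GTP"), "mass_action", "k3"),
)

# Conserved moieties of the full network (free + bound forms).  Each maps
# species name -> coefficient; the indicator vectors lie in the left null
# space of the stoichiometric matrix.
MOIETIES: dict[str, dict[str, int]] = {
    "5HTR4_total": {"5HTR4": 1, "5HTR4:5HT": 1},
    "MOR_total": {"MOR": 1, "MOR:OL": 1},
    "AC_total": {"AC": 1, "AC:alphaS_GTP": 1, "AC:alphaI_GTP": 1},
    "alphaS_total": {"alphaS_GDP:bgS": 1, "alphaS_GTP": 1, "alphaS_GDP": 1,
                     "AC:alphaS_GTP": 1},
    "bgS_total": {"alphaS_GDP:bgS": 1, "bgS": 1},
    "alphaI_total": {"alphaI_GDP:bgI": 1, "alphaI_GTP": 1, "alphaI_GDP": 1,
                     "AC:alphaI_GTP": 1},
    "bgI_total": {"alphaI_GDP:bgI": 1, "bgI": 1},
}


@dataclass(frozen=True)
class PulseTrain:
    """Optional pulsed 5HT release (emulating burst-like release from
    enterochromaffin cells).  While enabled, the release propensity (S2)
    is scaled by ``amplitude`` during the first ``duty`` fraction of each
    ``period_ms`` window and is zero otherwise."""

    amplitude: float = 2.0
    period_ms: float = 6e4
    duty: float = 0.5

    def factor(self, t: float) -> float:
        return self.amplitude if (t % self.period_ms) < self.duty * self.period_ms else 0.0


@dataclass(frozen=True)
class ReactionNetwork:
    """An assembled network: species (with initial concentrations),
    reactions, rate constants and, if the opioid arm is present, the drug.

    ``clamped`` lists species whose time derivative is forced to zero
    (bath/clamp conditions used by the dose-response assays).
    """

    species: tuple[SpeciesDef, ...]
    reactions: tuple[ReactionDef, ...]
    rates: RateTable
    drug: DrugSpec | None = None
    clamped: frozenset[str] = frozenset()
    pulse: PulseTrain | None = None
    release_ligand_on_unbind: bool = True

    # -- basic introspection --------------------------------------------
    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"species {name!r} not in network") from None

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_concentration for s in self.species])

    def with_initial(self, **concs: float) -> "ReactionNetwork":
        """Return a copy with the named initial concentrations replaced."""
        known = set(self.species_names)
        unknown = set(concs) - known
        if unknown:
            raise ConfigurationError(f"unknown species: {sorted(unknown)}")
        new_species = tuple(
            replace(s, initial_concentration=concs.get(s.name, s.initial_concentration))
            for s in self.species
        )
        return replace(self, species=new_species)

    def with_clamped(self, *names: str) -> "ReactionNetwork":
        for n in names:
            self.species_index(n)
        return replace(self, clamped=self.clamped | set(names))

    def rate_constant(self, name: str) -> float:
        """Resolve a rate-constant name, including the per-drug constants."""
        if name in ("kbindOL", "kunbindOL", "kdegOL"):
            if self.drug is None:
                raise ConfigurationError(
                    f"{name} requires a drug specification"
                )
            return {"kbindOL": self.drug.kon, "kunbindOL": self.drug.koff,
                    "kdegOL": self.drug.kdegOL}[name]
        try:
            return getattr(self.rates, name)
        except AttributeError:
            raise ConfigurationError(
                f"unknown rate constant {name!r}"
            ) from None

    def content_hash(self) -> str:
        """Stable hash of species, reactions, rates and drug (provenance)."""
        parts = [repr(self.species), repr(self.reactions), repr(self.rates),
                 repr(self.drug), repr(sorted(self.clamped)),
                 repr(self.pulse), repr(self.release_ligand_on_unbind)]
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]

    # -- compiled form for the integrator --------------------------------
    def compiled(self) -> "CompiledNetwork":
        return CompiledNetwork(self)


class CompiledNetwork:
    """Index-based, allocation-light evaluation of S and the propensities."""

    def __init__(self, network: ReactionNetwork):
        self.network = network
        self.n_species = len(network.species)
        self.n_reactions = len(network.reactions)
        self.S = stoichiometric_matrix(network).astype(float)
        self.rate_values = np.array(
            [network.rate_constant(r.rate_constant_name)
             for r in network.reactions]
        )
        names = network.species_names
        self.reactant_idx: list[tuple[int, ...]] = [
            tuple(names.index(sp) for sp in r.reactants)
            for r in network.reactions
        ]
        self.hill_j = next(
            (j for j, r in enumerate(network.reactions)
             if r.rate_law == "hill_production"), None
        )
        self.release_j = next(
            (j for j, r in enumerate(network.reactions) if r.id == "S2"), None
        )
        self.ac_idx = tuple(
            names.index(n) for n in ("AC", "AC:alphaS_GTP", "AC:alphaI_GTP")
            if n in names
        )
        self.ac_on_idx = names.index("AC:alphaS_GTP") if "AC:alphaS_GTP" in names else None
        self.clamp_mask = np.array(
            [s.name in network.clamped for s in network.species]
        )

    def propensities(self, state: np.ndarray, t: float = 0.0) -> np.ndarray:
        net = self.network
        pi = self.rate_values.copy()
        for j, idx in enumerate(self.reactant_idx):
            for i in idx:
                pi[j] *= state[i]
        if self.hill_j is not None:
            pi[self.hill_j] = self._hill_flux(state)
        if self.release_j is not None and net.pulse is not None:
            pi[self.release_j] *= net.pulse.factor(t)
        return pi

    def _hill_flux(self, state: np.ndarray) -> float:
        rates = self.network.rates
        if self.ac_on_idx is None:
            return 0.0
        total = sum(state[i] for i in self.ac_idx)
        if total <= 0:
            return 0.0
        ac_on = state[self.ac_on_idx] / total
        if ac_on <= 0:
            return 0.0
        h = (ac_on / rates.EC50_hill) ** rates.n_hill
        return rates.k2 * h / (1.0 + h)

    def rhs(self, t: float, state: np.ndarray) -> np.ndarray:
        dx = self.S @ self.propensities(state, t)
        if self.clamp_mask.any():
            dx[self.clamp_mask] = 0.0
        return dx


# --- operations -------------------------------------------------------------

def build_network(
    rates: RateTable | None = None,
    drug: DrugSpec | None = None,
    pathways: Iterable[str] = PATHWAYS,
    initial_overrides: Mapping[str, float] | None = None,
    release_ligand_on_unbind: bool = True,
    pulse: PulseTrain | None = None,
) -> ReactionNetwork:
    """Assemble the reaction network for the requested pathway blocks.

    The full model (serotonin + opioid + competing) has 25 reactions and
    20 species.  The competing block requires both upstream arms because
    its displacement reaction couples activated alphaI to the stimulatory
    AC complex.  Requesting the opioid arm without a drug is an error
    since the opioid binding kinetics are per-ligand.
    """
    rates = rates or RateTable()
    requested = set(pathways)
    unknown = requested - set(PATHWAYS)
    if unknown:
        raise ConfigurationError(f"unknown pathway(s): {sorted(unknown)}")
    if not requested:
        raise ConfigurationError("at least one pathway must be requested")
    if "competing" in requested and not {"serotonin", "opioid"} <= requested:
        raise ConfigurationError(
            "the competing block requires both the serotonin and opioid arms"
        )
    if "opioid" in requested and drug is None:
        raise ConfigurationError("the opioid pathway requires a drug spec")

    species_rows: list[tuple[str, float, str]] = []
    reactions: list[ReactionDef] = []
    if "serotonin" in requested:
        species_rows += list(_SEROTONIN_SPECIES)
        reactions += list(_SEROTONIN_REACTIONS)
    if "opioid" in requested:
        species_rows += [r for r in _OPIOID_SPECIES
                         if r[0] not in {n for n, _, _ in species_rows}]
        reactions += list(_OPIOID_REACTIONS)
        if drug is not None and drug.degrade_in_blood:
            reactions.append(
                ReactionDef("O4b", ("OL_Blood",), (), "mass_action", "kdegOL")
            )
    if "competing" in requested:
        species_rows += list(_CAMP_SPECIES)
        reactions += list(_COMPETING_REACTIONS)

    if not release_ligand_on_unbind:
        # literal table reading: the ligand is destroyed on unbinding
        reactions = [
            replace(r, products=("5HTR4",)) if r.id == "S7"
            else replace(r, products=("MOR",)) if r.id == "O2"
            else r
            for r in reactions
        ]
    else:
        reactions = [
            replace(r, products=("5HTR4", "5HT")) if r.id == "S7"
            else replace(r, products=("MOR", "OL")) if r.id == "O2"
            else r
            for r in reactions
        ]

    overrides = dict(initial_overrides or {})
    unknown_sp = set(overrides) - {n for n, _, _ in species_rows}
    if unknown_sp:
        raise ConfigurationError(
            f"initial-concentration override for unknown species: "
            f"{sorted(unknown_sp)}"
        )
    species = tuple(
        SpeciesDef(name, overrides.get(name, x0), tag)
        for name, x0, tag in species_rows
    )
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        raise ConfigurationError("duplicate species names")

    net = ReactionNetwork(
        species=species, reactions=tuple(reactions), rates=rates, drug=drug,
        release_ligand_on_unbind=release_ligand_on_unbind, pulse=pulse,
    )
    # validate rate-constant references and species references eagerly
    for r in net.reactions:
        net.rate_constant(r.rate_constant_name)
        for sp in r.reactants + r.products:
            net.species_index(sp)
    return net


def stoichiometric_matrix(network: ReactionNetwork) -> np.ndarray:
    """Net-production matrix S with S[i, j] the net change of species i in
    reaction j (catalysts cancel); column order follows reaction order."""
    names = network.species_names
    S = np.zeros((len(names), len(network.reactions)), dtype=int)
    for j, r in enumerate(network.reactions):
        for sp in r.reactants:
            S[names.index(sp), j] -= 1
        for sp in r.products:
            S[names.index(sp), j] += 1
    return S


def propensities(
    network: ReactionNetwork, state: Sequence[float], t: float = 0.0
) -> np.ndarray:
    """Reaction fluxes pi(x, t) in uM/ms.

    Mass-action reactions return k * prod(reactant concentrations) (a
    zeroth-order source returns its constant flux); C1 returns the Hill
    production term evaluated at the activated AC fraction of ``state``.
    """
    state = np.asarray(state, dtype=float)
    if len(state) != len(network.species):
        raise ValueError(
            f"state has length {len(state)}, expected {len(network.species)}"
        )
    if (state < 0).any():
        bad = network.species_names[int(np.argmin(state))]
        raise ValueError(f"negative concentration for {bad}")
    return network.compiled().propensities(state, t)


def conserved_totals(
    network: ReactionNetwork, state: Sequence[float]
) -> dict[str, float]:
    """Totals of the conserved moieties (receptors, G-protein subunits and
    AC across their free and bound forms) present in the network."""
    state = np.asarray(state, dtype=float)
    names = network.species_names
    out: dict[str, float] = {}
    for moiety, coeffs in MOIETIES.items():
        if all(sp in names for sp in coeffs):
            out[moiety] = float(
                sum(c * state[names.index(sp)] for sp, c in coeffs.items())
            )
    return out
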