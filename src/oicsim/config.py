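"""Run configuration: defaults, structured overrides, provenance.

A configuration file (YAML) may override any rate constant, any initial
concentration, any drug definition, the solver options and the scenario
parameters.  Unknown keys are rejected with the offending key path.  The
fully-resolved configuration and its hash are attached to results for
provenance; a single top-level seed fans out deterministically to
per-task seeds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .engine import DAY_MS, HOUR_MS, SolverOptions
from .network import (
    ConfigurationError, DrugSpec, RateTable, ReactionNetwork,
    default_drugs, default_initial_concentrations,
)

__all__ = [
    "RunConfig", "ConfigurationError", "load_config",
    "export_parameter_sheet",
]

_DRUG_KEYS = {"Kd", "koff", "kon", "kdegOL", "dose", "dose_compartment",
              "degrade_in_blood"}
_SOLVER_KEYS = {"rel_tol", "abs_tol", "max_step", "method_hint"}
_SCENARIO_KEYS = {"pre_equilibration_hours", "horizon_days",
                  "serotonin_drive"}
_ASSAY_KEYS = {"readout_minutes", "agonist_window_hours",
               "receptor_density"}
_TOP_KEYS = {"rates", "initial_concentrations", "drugs", "solver",
             "scenario", "assays", "release_ligand_on_unbind", "seed",
             "output_dir"}


@dataclass
class RunConfig:
    """Fully-resolved run configuration (defaults merged with overrides)."""

    rates: RateTable = field(default_factory=RateTable)
    initial_concentrations: dict[str, float] = field(
        default_factory=default_initial_concentrations)
    drugs: dict[str, DrugSpec] = field(default_factory=default_drugs)
    solver: SolverOptions = field(default_factory=SolverOptions)
    pre_equilibration_hours: float = 24.0
    horizon_days: float = 14.0
    serotonin_drive: str = "continuous"
    readout_minutes: float = 30.0
    agonist_window_hours: float = 4.0
    receptor_density: float = 5e-6
    release_ligand_on_unbind: bool = True
    seed: int = 0
    output_dir: str = "results"

    @property
    def pre_equilibration_ms(self) -> float:
        return self.pre_equilibration_hours * HOUR_MS

    @property
    def horizon_ms(self) -> float:
        return self.horizon_days * DAY_MS

    @property
    def readout_ms(self) -> float:
        return self.readout_minutes * 60e3

    def drug(self, name: str) -> DrugSpec:
        try:
            return self.drugs[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown drug {name!r}; configured: {sorted(self.drugs)}"
            ) from None

    def spawn_seed(self, task: str) -> int:
        """Deterministic per-task seed derived from the top-level seed."""
        digest = hashlib.sha256(f"{self.seed}:{task}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2 ** 31)

    def resolved_dict(self) -> dict:
        out = {
            "rates": asdict(self.rates),
            "initial_concentrations": dict(self.initial_concentrations),
            "drugs": {name: asdict(d) for name, d in self.drugs.items()},
            "solver": asdict(self.solver),
            "scenario": {
                "pre_equilibration_hours": self.pre_equilibration_hours,
                "horizon_days": self.horizon_days,
                "serotonin_drive": self.serotonin_drive,
            },
            "assays": {
                "readout_minutes": self.readout_minutes,
                "agonist_window_hours": self.agonist_window_hours,
                "receptor_density": self.receptor_density,
            },
            "release_ligand_on_unbind": self.release_ligand_on_unbind,
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def write_provenance(self, path: str | Path) -> None:
        payload = self.resolved_dict()
        payload["config_hash"] = self.config_hash()
        Path(path).write_text(json.dumps(payload, indent=2, default=str))


def _require_mapping(value: Any, path: str) -> Mapping:
    if value is None:
        return {}
    if not isinstance(value, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping")
    return value


def _check_keys(section: Mapping, allowed: set[str], path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigurationError(f"unknown key {path}.{key}" if path
                                 else f"unknown key {key}")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML configuration and merge it over the defaults.

    An empty (or absent) file yields the full defaults; schema
    violations raise :class:`ConfigurationError` naming the key path.
    """
    raw: Mapping = {}
    if path is not None:
        text = Path(path).read_text()
        raw = _require_mapping(yaml.safe_load(text) or {}, "<top>")
    _check_keys(raw, _TOP_KEYS, "")

    rates = RateTable().with_overrides(
        **{k: float(v) for k, v in
           _require_mapping(raw.get("rates"), "rates").items()}
    )

    initials = default_initial_concentrations()
    given = _require_mapping(raw.get("initial_concentrations"),
                             "initial_concentrations")
    unknown_sp = set(given) - set(initials)
    if unknown_sp:
        raise ConfigurationError(
            f"unknown key initial_concentrations.{sorted(unknown_sp)[0]}"
        )
    initials.update({k: float(v) for k, v in given.items()})

    drugs = default_drugs()
    for name, spec in _require_mapping(raw.get("drugs"), "drugs").items():
        spec = _require_mapping(spec, f"drugs.{name}")
        _check_keys(spec, _DRUG_KEYS, f"drugs.{name}")
        base = drugs.get(name)
        merged = ({} if base is None else
                  {f.name: getattr(base, f.name) for f in dc_fields(base)
                   if f.name != "name"})
        merged.update(spec)
        if "Kd" not in merged:
            raise ConfigurationError(f"drugs.{name}: Kd is required")
        # kon must track koff/Kd unless explicitly overridden together
        if ("koff" in spec or "Kd" in spec) and "kon" not in spec:
            merged.pop("kon", None)
        drugs[name] = DrugSpec(name=name, **merged)

    solver_raw = dict(_require_mapping(raw.get("solver"), "solver"))
    _check_keys(solver_raw, _SOLVER_KEYS, "solver")
    solver = SolverOptions(**{**{f.name: getattr(SolverOptions(), f.name)
                                 for f in dc_fields(SolverOptions)},
                              **solver_raw})

    scenario = dict(_require_mapping(raw.get("scenario"), "scenario"))
    _check_keys(scenario, _SCENARIO_KEYS, "scenario")
    assays = dict(_require_mapping(raw.get("assays"), "assays"))
    _check_keys(assays, _ASSAY_KEYS, "assays")

    return RunConfig(
        rates=rates,
        initial_concentrations=initials,
        drugs=drugs,
        solver=solver,
        pre_equilibration_hours=float(
            scenario.get("pre_equilibration_hours", 24.0)),
        horizon_days=float(scenario.get("horizon_days", 14.0)),
        serotonin_drive=str(scenario.get("serotonin_drive", "continuous")),
        readout_minutes=float(assays.get("readout_minutes", 30.0)),
        agonist_window_hours=float(assays.get("agonist_window_hours", 4.0)),
        receptor_density=float(assays.get("receptor_density", 5e-6)),
        release_ligand_on_unbind=bool(
            raw.get("release_ligand_on_unbind", True)),
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "results")),
    )


def export_parameter_sheet(network: ReactionNetwork) -> pd.DataFrame:
    """Flat parameter sheet: initial concentrations and rate constants
    (mirrors the model's species/rates tables)."""
    rows = [
        {"kind": "initial_concentration", "name": s.name,
         "value": s.initial_concentration, "units": "uM"}
        for s in network.species
    ]
    seen = set()
    for r in network.reactions:
        name = r.rate_constant_name
        if name in seen:
            continue
        seen.add(name)
        rows.append({"kind": "rate_constant", "name": name,
                     "value": network.rate_constant(name),
                     "units": "ms^-1 or uM^-1 ms^-1"})
    return pd.DataFrame(rows)
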