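"""Minimal SBML Level 3 writer/reader for the reaction network.

The writer emits standard SBML core (compartment, species with initial
concentrations, parameters, reactions with mass-action or Hill kinetic
laws in MathML) so the model can be exchanged with external simulators.
A small annotation block under the package's own namespace carries the
rate-law tags, the drug specification and the unbinding convention, so
an export -> import round trip reproduces the network exactly (species,
parameters, stoichiometry and kinetic laws).
"""

from __future__ import annotations

import re
from pathlib import Path

from lxml import etree

from .network import (
    ConfigurationError, DrugSpec, RateTable, ReactionDef, ReactionNetwork,
    SpeciesDef,
)

__all__ = ["write_sbml", "read_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
OICSIM_NS = "https://oicsim.readthedocs.io/sbml"

_NSMAP = {None: SBML_NS}
_Q = lambda tag: f"{{{SBML_NS}}}{tag}"
_QM = lambda tag: f"{{{MATHML_NS}}}{tag}"
_QO = lambda tag: f"{{{OICSIM_NS}}}{tag}"

_DRUG_RATE_NAMES = ("kbindOL", "kunbindOL", "kdegOL")


def _sid(name: str) -> str:
    """Sanitise a species/parameter name into a valid SBML SId."""
    sid = re.sub(r"[^A-Za-z0-9_]", "_", name)
    if not re.match(r"[A-Za-z_]", sid):
        sid = "s_" + sid
    return sid


def _multiset(names: tuple[str, ...]) -> dict[str, int]:
    out: dict[str, int] = {}
    for n in names:
        out[n] = out.get(n, 0) + 1
    return out


def _mathml_mass_action(k_name: str, reactants: tuple[str, ...]) -> etree._Element:
    math = etree.Element(_QM("math"), nsmap={None: MATHML_NS})
    if not reactants:
        ci = etree.SubElement(math, _QM("ci"))
        ci.text = f" {_sid(k_name)} "
        return math
    apply = etree.SubElement(math, _QM("apply"))
    etree.SubElement(apply, _QM("times"))
    for name in (k_name,) + reactants:
        ci = etree.SubElement(apply, _QM("ci"))
        ci.text = f" {_sid(name)} "
    return math


def _mathml_hill(rates: RateTable) -> etree._Element:
    """k2 * h/(1+h) with h = (AC_on/EC50)^n and AC_on the stimulated
    fraction of the AC pool, written as explicit MathML."""
    def ci(parent, name):
        el = etree.SubElement(parent, _QM("ci"))
        el.text = f" {name} "
        return el

    def cn(parent, value):
        el = etree.SubElement(parent, _QM("cn"))
        el.text = f" {value!r} "
        return el

    def apply(parent, op):
        ap = etree.SubElement(parent, _QM("apply"))
        etree.SubElement(ap, _QM(op))
        return ap

    math = etree.Element(_QM("math"), nsmap={None: MATHML_NS})
    top = apply(math, "times")
    ci(top, _sid("k2"))
    frac = apply(top, "divide")

    def hill_term(parent):
        power = apply(parent, "power")
        ratio = apply(power, "divide")
        acon = apply(ratio, "divide")
        ci(acon, _sid("AC:alphaS_GTP"))
        total = apply(acon, "plus")
        for sp in ("AC", "AC:alphaS_GTP", "AC:alphaI_GTP"):
            ci(total, _sid(sp))
        ci(ratio, _sid("EC50_hill"))
        ci(power, _sid("n_hill"))

    hill_term(frac)
    denom = apply(frac, "plus")
    cn(denom, 1.0)
    hill_term(denom)
    return math


def write_sbml(network: ReactionNetwork, path: str | Path | None = None) -> str:
    """Serialise the network to an SBML L3 document; optionally write it
    to ``path``.  Clamped species are marked as boundary conditions."""
    root = etree.Element(_Q("sbml"), nsmap=_NSMAP)
    root.set("level", "3")
    root.set("version", "2")
    model = etree.SubElement(root, _Q("model"))
    model.set("id", "oicsim_network")
    model.set("substanceUnits", "micromole")
    model.set("timeUnits", "millisecond")

    ann = etree.SubElement(model, _Q("annotation"))
    meta = etree.SubElement(ann, _QO("network"), nsmap={"oicsim": OICSIM_NS})
    meta.set("releaseLigandOnUnbind",
             str(network.release_ligand_on_unbind).lower())
    if network.drug is not None:
        d = network.drug
        drug_el = etree.SubElement(meta, _QO("drug"))
        for attr in ("name", "Kd", "koff", "kon", "kdegOL", "dose",
                     "dose_compartment"):
            drug_el.set(attr, str(getattr(d, attr)))
        drug_el.set("degrade_in_blood", str(d.degrade_in_blood).lower())

    comps = etree.SubElement(model, _Q("listOfCompartments"))
    comp = etree.SubElement(comps, _Q("compartment"))
    comp.set("id", "cell")
    comp.set("size", "1")
    comp.set("constant", "true")

    species_el = etree.SubElement(model, _Q("listOfSpecies"))
    for s in network.species:
        el = etree.SubElement(species_el, _Q("species"))
        el.set("id", _sid(s.name))
        el.set("name", s.name)
        el.set("compartment", "cell")
        el.set("initialConcentration", repr(s.initial_concentration))
        el.set("hasOnlySubstanceUnits", "false")
        el.set("boundaryCondition",
               "true" if s.name in network.clamped else "false")
        el.set("constant", "false")
        el.set(_QO("pathwayTag"), s.pathway_tag)

    params_el = etree.SubElement(model, _Q("listOfParameters"))
    written: set[str] = set()
    for r in network.reactions:
        name = r.rate_constant_name
        if name in written:
            continue
        written.add(name)
        el = etree.SubElement(params_el, _Q("parameter"))
        el.set("id", _sid(name))
        el.set("name", name)
        el.set("value", repr(network.rate_constant(name)))
        el.set("constant", "true")
    for extra in ("EC50_hill", "n_hill"):
        if extra not in written:
            el = etree.SubElement(params_el, _Q("parameter"))
            el.set("id", _sid(extra))
            el.set("name", extra)
            el.set("value", repr(getattr(network.rates, extra)))
            el.set("constant", "true")

    reactions_el = etree.SubElement(model, _Q("listOfReactions"))
    for r in network.reactions:
        el = etree.SubElement(reactions_el, _Q("reaction"))
        el.set("id", _sid(r.id))
        el.set("reversible", "false")
        el.set(_QO("rateLaw"), r.rate_law)
        el.set(_QO("rateConstant"), r.rate_constant_name)
        for tag, names in (("listOfReactants", r.reactants),
                           ("listOfProducts", r.products)):
            if not names:
                continue
            lst = etree.SubElement(el, _Q(tag))
            for sp, count in _multiset(names).items():
                ref = etree.SubElement(lst, _Q("speciesReference"))
                ref.set("species", _sid(sp))
                ref.set("stoichiometry", str(count))
                ref.set("constant", "true")
        kl = etree.SubElement(el, _Q("kineticLaw"))
        if r.rate_law == "hill_production":
            kl.append(_mathml_hill(network.rates))
        else:
            kl.append(_mathml_mass_action(r.rate_constant_name, r.reactants))

    text = etree.tostring(root, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()
    if path is not None:
        Path(path).write_text(text)
    return text


def read_sbml(source: str | Path) -> ReactionNetwork:
    """Rebuild a :class:`ReactionNetwork` from a document produced by
    :func:`write_sbml` (species, parameters, reactions, drug, clamps)."""
    text = (Path(source).read_text()
            if isinstance(source, Path) or (isinstance(source, str)
                                            and not source.lstrip().startswith("<"))
            else str(source))
    root = etree.fromstring(text.encode())
    model = root.find(_Q("model"))
    if model is None:
        raise ConfigurationError("document has no <model>")

    release = True
    drug = None
    meta = model.find(f"{_Q('annotation')}/{_QO('network')}")
    if meta is not None:
        release = meta.get("releaseLigandOnUnbind", "true") == "true"
        drug_el = meta.find(_QO("drug"))
        if drug_el is not None:
            drug = DrugSpec(
                name=drug_el.get("name"),
                Kd=float(drug_el.get("Kd")),
                koff=float(drug_el.get("koff")),
                kon=float(drug_el.get("kon")),
                kdegOL=float(drug_el.get("kdegOL")),
                dose=float(drug_el.get("dose")),
                dose_compartment=drug_el.get("dose_compartment", "blood"),
                degrade_in_blood=drug_el.get("degrade_in_blood") == "true",
            )

    id_to_name: dict[str, str] = {}
    species: list[SpeciesDef] = []
    clamped: set[str] = set()
    for el in model.findall(f"{_Q('listOfSpecies')}/{_Q('species')}"):
        name = el.get("name") or el.get("id")
        id_to_name[el.get("id")] = name
        species.append(SpeciesDef(
            name=name,
            initial_concentration=float(el.get("initialConcentration", "0")),
            pathway_tag=el.get(_QO("pathwayTag"), "shared"),
        ))
        if el.get("boundaryCondition") == "true":
            clamped.add(name)

    param_values: dict[str, float] = {}
    for el in model.findall(f"{_Q('listOfParameters')}/{_Q('parameter')}"):
        param_values[el.get("name") or el.get("id")] = float(el.get("value"))
    rate_fields = {f for f in RateTable().__dict__}
    rates = RateTable().with_overrides(
        **{k: v for k, v in param_values.items() if k in rate_fields}
    )

    reactions: list[ReactionDef] = []
    for el in model.findall(f"{_Q('listOfReactions')}/{_Q('reaction')}"):

        def refs(tag: str) -> tuple[str, ...]:
            out: list[str] = []
            for ref in el.findall(f"{_Q(tag)}/{_Q('speciesReference')}"):
                name = id_to_name[ref.get("species")]
                out.extend([name] * int(float(ref.get("stoichiometry", "1"))))
            return tuple(out)

        rid = el.get("id")
        reactions.append(ReactionDef(
            id=rid,
            reactants=refs("listOfReactants"),
            products=refs("listOfProducts"),
            rate_law=el.get(_QO("rateLaw"), "mass_action"),
            rate_constant_name=el.get(_QO("rateConstant"), ""),
        ))

    return ReactionNetwork(
        species=tuple(species), reactions=tuple(reactions), rates=rates,
        drug=drug, clamped=frozenset(clamped),
        release_ligand_on_unbind=release,
    )
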