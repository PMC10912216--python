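"""Minimal SBML Level 3 export/import of the mass-action network.

Writes the network (species, parameters, reactions with mass-action kinetic
laws in MathML) as SBML L3V2 core and reads the same dialect back.  The writer
covers exactly the constructs this package produces — single compartment,
integer stoichiometries, rate = k * product(species^power) — which is enough
for a faithful round-trip of the reference build and for exchange with
SBML-aware tools.
"""

from __future__ import annotations

from lxml import etree

from .network import Reaction, ReactionNetwork, Species

__all__ = ["write_sbml", "read_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def write_sbml(net: ReactionNetwork, path: str,
               parameters: dict[str, float] | None = None,
               initial_amounts: dict[str, float] | None = None) -> None:
    """Serialize a network (optionally with parameter values) to SBML L3."""
    parameters = parameters or {}
    initial_amounts = initial_amounts or {}
    E = etree.SubElement
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap={None: SBML_NS},
                         attrib={"level": "3", "version": "2"})
    model = E(root, f"{{{SBML_NS}}}model", id="hgf_signaling")

    comps = E(model, f"{{{SBML_NS}}}listOfCompartments")
    E(comps, f"{{{SBML_NS}}}compartment", id="cell", size="1", constant="true")

    sp_list = E(model, f"{{{SBML_NS}}}listOfSpecies")
    for s in net.species:
        E(sp_list, f"{{{SBML_NS}}}species", id=s.name, compartment="cell",
          initialAmount=repr(float(initial_amounts.get(s.name, 0.0))),
          hasOnlySubstanceUnits="true", boundaryCondition="false",
          constant="false", metaid=f"role_{s.role}_{s.initial_source}")

    par_list = E(model, f"{{{SBML_NS}}}listOfParameters")
    seen = []
    for r in net.reactions:
        if r.rate_parameter not in seen:
            seen.append(r.rate_parameter)
            E(par_list, f"{{{SBML_NS}}}parameter", id=r.rate_parameter,
              value=repr(float(parameters.get(r.rate_parameter, 1.0))),
              constant="true")

    rx_list = E(model, f"{{{SBML_NS}}}listOfReactions")
    for r in net.reactions:
        rx = E(rx_list, f"{{{SBML_NS}}}reaction", id=r.name, reversible="false")
        if r.reactants:
            lst = E(rx, f"{{{SBML_NS}}}listOfReactants")
            for name, coeff in r.reactants.items():
                E(lst, f"{{{SBML_NS}}}speciesReference", species=name,
                  stoichiometry=str(coeff), constant="true")
        if r.products:
            lst = E(rx, f"{{{SBML_NS}}}listOfProducts")
            for name, coeff in r.products.items():
                E(lst, f"{{{SBML_NS}}}speciesReference", species=name,
                  stoichiometry=str(coeff), constant="true")
        if r.modifiers:
            lst = E(rx, f"{{{SBML_NS}}}listOfModifiers")
            for name, power in r.modifiers.items():
                E(lst, f"{{{SBML_NS}}}modifierSpeciesReference", species=name,
                  metaid=f"power_{r.name}_{name}_{power}")
        law = E(rx, f"{{{SBML_NS}}}kineticLaw")
        math = E(law, f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
        apply_ = E(math, f"{{{MATHML_NS}}}apply")
        E(apply_, f"{{{MATHML_NS}}}times")
        ci = E(apply_, f"{{{MATHML_NS}}}ci")
        ci.text = r.rate_parameter
        for name, coeff in r.reactants.items():
            for _ in range(coeff):
                ci = E(apply_, f"{{{MATHML_NS}}}ci")
                ci.text = name
        for name, power in r.modifiers.items():
            for _ in range(power):
                ci = E(apply_, f"{{{MATHML_NS}}}ci")
                ci.text = name
    etree.ElementTree(root).write(path, pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


def read_sbml(path: str) -> tuple[ReactionNetwork, dict[str, float]]:
    """Read a network written by :func:`write_sbml` (plus parameter values)."""
    tree = etree.parse(path)
    ns = {"s": SBML_NS, "m": MATHML_NS}
    species = []
    for el in tree.findall(".//s:listOfSpecies/s:species", ns):
        meta = el.get("metaid", "role_kinase_derived")
        _, role, source = meta.split("_", 2)
        species.append(Species(el.get("id"), role, source))
    params = {el.get("id"): float(el.get("value", "1.0"))
              for el in tree.findall(".//s:listOfParameters/s:parameter", ns)}
    param_ids = set(params)
    reactions = []
    for rx in tree.findall(".//s:listOfReactions/s:reaction", ns):
        reactants: dict[str, int] = {}
        products: dict[str, int] = {}
        for el in rx.findall("s:listOfReactants/s:speciesReference", ns):
            reactants[el.get("species")] = int(float(el.get("stoichiometry", "1")))
        for el in rx.findall("s:listOfProducts/s:speciesReference", ns):
            products[el.get("species")] = int(float(el.get("stoichiometry", "1")))
        cis = [el.text for el in rx.findall("s:kineticLaw/m:math/m:apply/m:ci", ns)]
        rate_parameter = next(c for c in cis if c in param_ids)
        monomial: dict[str, int] = {}
        for c in cis:
            if c != rate_parameter:
                monomial[c] = monomial.get(c, 0) + 1
        modifiers = {name: power - reactants.get(name, 0)
                     for name, power in monomial.items()
                     if power - reactants.get(name, 0) > 0}
        reactions.append(Reaction(rx.get("id"), reactants, products,
                                  rate_parameter, modifiers))
    return ReactionNetwork(species, reactions), params
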