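"""SBML Level 3 export and re-import of the reaction network.

The exporter writes the full 22-reaction network: the 13 dynamic species,
the four conserved complements (so that SBML semantics reproduce the moiety
conservation through stoichiometry alone), the four clamped boundary species
and every rate law as content MathML built from a small expression AST.

The importer parses the document back with lxml and evaluates the kinetic
laws with a self-contained content-MathML evaluator, so a round trip checks
the *symbolic* rate laws, not merely the parameter values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lxml import etree

from .kinetics import COMPLEMENTS, FULL_STOICHIOMETRY, SPECIES, ClampedEnvironment
from .params import ParameterSet

__all__ = ["export_sbml", "import_sbml", "SbmlModel", "RATE_LAWS"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_BOUNDARY = ("fum", "suc", "H", "O2")

# Expression AST: str -> symbol, number -> constant,
# tuple ("op", *args) with op in {plus, minus, times, divide, power, exp}.
Expr = object


def _mass_action(kf: str, keq: str, fwd: tuple, rev: tuple) -> Expr:
    return ("times", kf, ("minus", ("times",) + fwd, ("divide", ("times",) + rev, keq)))


def _bv_exponent(sign: float, coeff: Expr) -> Expr:
    # exp(sign * coeff * E_out / vT)
    return ("exp", ("divide", ("times", sign, coeff, "E_out"), "vT"))


#: Rate-law ASTs for all 22 reactions, in terms of species ids, clamped ids
#: and parameter ids (k1..k20, keq1..keq20, alpha, vT, E_out, Vmax21, Km21,
#: k22).  These mirror the mass-action/Butler-Volmer laws of the kinetics
#: module symbolically.
RATE_LAWS: dict[int, Expr] = {
    1: (
        "times",
        "k1",
        (
            "minus",
            ("times", "fes3_ox", _bv_exponent(-1.0, "alpha")),
            (
                "divide",
                ("times", "fes3_red", ("exp", ("divide", ("times", ("minus", 1.0, "alpha"), "E_out"), "vT"))),
                "keq1",
            ),
        ),
    ),
    2: _mass_action("k2", "keq2", ("fes4_ox", "fes3_red"), ("fes4_red", "fes3_ox")),
    3: _mass_action("k3", "keq3", ("fes2_ox", "fes4_red"), ("fes2_red", "fes4_ox")),
    4: _mass_action("k4", "keq4", ("fad", "fum"), ("fad_fum",)),
    5: _mass_action("k5", "keq5", ("fad_fum", "fes2_red", "H"), ("fadh_fum", "fes2_ox")),
    6: _mass_action("k6", "keq6", ("fadh_fum", "fes2_red", "H"), ("fadh2_fum", "fes2_ox")),
    7: _mass_action("k7", "keq7", ("fadh2_fum",), ("fad_suc",)),
    8: _mass_action("k8", "keq8", ("fad_suc",), ("fad", "suc")),
    9: _mass_action("k9", "keq9", ("fad", "fes2_red", "H"), ("fadh", "fes2_ox")),
    10: _mass_action("k10", "keq10", ("fadh", "fum"), ("fadh_fum",)),
    11: _mass_action("k11", "keq11", ("fadh", "fes2_red", "H"), ("fadh2", "fes2_ox")),
    12: _mass_action("k12", "keq12", ("fadh2", "fum"), ("fadh2_fum",)),
    13: _mass_action("k13", "keq13", ("fad_suc", "fes2_red", "H"), ("fadh_suc", "fes2_ox")),
    14: _mass_action("k14", "keq14", ("fadh_suc",), ("fadh", "suc")),
    15: _mass_action("k15", "keq15", ("fadh_suc", "fes2_red", "H"), ("fadh2_suc", "fes2_ox")),
    16: _mass_action("k16", "keq16", ("fadh2_suc",), ("fadh2", "suc")),
    17: _mass_action("k17", "keq17", ("fadh2", "O2"), ("fad", "h2o2")),
    18: _mass_action("k18", "keq18", ("fadh2", "O2"), ("fadh", "superoxide", "H")),
    19: _mass_action("k19", "keq19", ("fadh", "O2"), ("fad", "superoxide", "H")),
    20: _mass_action("k20", "keq20", ("fes3_red", "O2"), ("fes3_ox", "superoxide")),
    21: ("divide", ("times", "Vmax21", "superoxide"), ("plus", "Km21", "superoxide")),
    22: ("times", "k22", "h2o2"),
}


def _expr_to_mathml(expr: Expr, parent: etree._Element) -> None:
    m = "{%s}" % MATHML_NS
    if isinstance(expr, str):
        ci = etree.SubElement(parent, m + "ci")
        ci.text = f" {expr} "
        return
    if isinstance(expr, (int, float)):
        cn = etree.SubElement(parent, m + "cn")
        cn.text = f" {float(expr):.17g} "
        return
    op, *args = expr
    apply_el = etree.SubElement(parent, m + "apply")
    etree.SubElement(apply_el, m + op)
    for a in args:
        _expr_to_mathml(a, apply_el)


def _eval_mathml(node: etree._Element, values: dict[str, float]) -> float:
    tag = etree.QName(node).localname
    if tag == "ci":
        return values[node.text.strip()]
    if tag == "cn":
        if node.get("type") == "e-notation":
            mantissa = float(node.text.strip())
            exp = float(node[0].tail.strip())
            return mantissa * 10.0**exp
        return float(node.text.strip())
    if tag == "apply":
        op = etree.QName(node[0]).localname
        args = [_eval_mathml(c, values) for c in node[1:]]
        if op == "plus":
            return sum(args)
        if op == "minus":
            return -args[0] if len(args) == 1 else args[0] - args[1]
        if op == "times":
            return math.prod(args)
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
        if op == "exp":
            return math.exp(args[0])
        raise ValueError(f"unsupported MathML operator: {op}")
    raise ValueError(f"unsupported MathML node: {tag}")


def _parameter_values(ps: ParameterSet, env: ClampedEnvironment) -> dict[str, float]:
    vals: dict[str, float] = {
        "alpha": ps.constants.alpha,
        "vT": ps.constants.thermal_voltage_mV,
        "E_out": env.E_out,
        "Vmax21": ps.sod_Vmax21,
        "Km21": ps.sod_Km21,
        "k22": ps.k22,
    }
    for i in range(1, 21):
        vals[f"k{i}"] = ps.k[i]
        vals[f"keq{i}"] = ps.keq[i]
    return vals


def export_sbml(
    ps: ParameterSet,
    env: ClampedEnvironment | None = None,
    path: str | None = None,
    initial_state: np.ndarray | None = None,
) -> bytes:
    """Serialize the network as an SBML Level 3 Version 2 document.

    Returns the document bytes; writes them to ``path`` when given.  The
    clamped environment supplies the boundary-species concentrations and the
    electrode potential; the initial state defaults to fully oxidized pools.
    """
    env = env or ClampedEnvironment()
    y0 = np.zeros(len(SPECIES)) if initial_state is None else np.asarray(initial_state)

    nsmap = {None: SBML_NS}
    s = "{%s}" % SBML_NS
    root = etree.Element(s + "sbml", nsmap=nsmap, level="3", version="2")
    model = etree.SubElement(root, s + "model", id=f"sdh_reverse_{ps.label}")
    model.set("substanceUnits", "micromole")
    model.set("timeUnits", "second")

    comps = etree.SubElement(model, s + "listOfCompartments")
    etree.SubElement(
        comps, s + "compartment", id="imb", spatialDimensions="3", size="1", constant="true"
    )

    species_el = etree.SubElement(model, s + "listOfSpecies")
    from .kinetics import complements as _complements

    comp0 = _complements(y0, ps)
    init = {name: float(v) for name, v in zip(SPECIES, y0)}
    init.update(comp0)
    clamped = {"fum": env.fum, "suc": env.suc, "H": env.Hplus, "O2": env.O2}
    for sid in list(SPECIES) + list(COMPLEMENTS):
        etree.SubElement(
            species_el, s + "species", id=sid, compartment="imb",
            initialConcentration=f"{init[sid]:.17g}",
            hasOnlySubstanceUnits="false", boundaryCondition="false", constant="false",
        )
    for sid in _BOUNDARY:
        etree.SubElement(
            species_el, s + "species", id=sid, compartment="imb",
            initialConcentration=f"{clamped[sid]:.17g}",
            hasOnlySubstanceUnits="false", boundaryCondition="true", constant="false",
        )

    params_el = etree.SubElement(model, s + "listOfParameters")
    for pid, value in _parameter_values(ps, env).items():
        etree.SubElement(
            params_el, s + "parameter", id=pid, value=f"{value:.17g}", constant="true"
        )

    rxns = etree.SubElement(model, s + "listOfReactions")
    all_ids = list(SPECIES) + list(COMPLEMENTS)
    for rid in range(1, 23):
        col = FULL_STOICHIOMETRY[:, rid - 1]
        rxn = etree.SubElement(
            rxns, s + "reaction", id=f"R{rid}", reversible="true" if rid <= 20 else "false"
        )
        reactants = etree.SubElement(rxn, s + "listOfReactants")
        products = etree.SubElement(rxn, s + "listOfProducts")
        for sid, coef in zip(all_ids, col):
            if coef < 0:
                etree.SubElement(
                    reactants, s + "speciesReference", species=sid,
                    stoichiometry=f"{-coef:g}", constant="true",
                )
            elif coef > 0:
                etree.SubElement(
                    products, s + "speciesReference", species=sid,
                    stoichiometry=f"{coef:g}", constant="true",
                )
        law = etree.SubElement(rxn, s + "kineticLaw")
        math_el = etree.SubElement(law, "{%s}math" % MATHML_NS)
        _expr_to_mathml(RATE_LAWS[rid], math_el)

    doc = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(doc)
    return doc


@dataclass
class SbmlModel:
    """A parsed SBML document: species initials, parameters and rate laws."""

    species: dict[str, float]
    boundary: dict[str, float]
    parameters: dict[str, float]
    laws: dict[int, etree._Element]
    stoichiometry: dict[int, dict[str, float]]

    def evaluate_rates(self, state: dict[str, float] | None = None) -> np.ndarray:
        """V1..V22 (uM/s) at the stored initials or an overriding state."""
        values = dict(self.boundary)
        values.update(self.parameters)
        values.update(self.species)
        if state:
            values.update(state)
        return np.array(
            [_eval_mathml(self.laws[i][0], values) for i in range(1, 23)]
        )


def import_sbml(source: str | bytes) -> SbmlModel:
    """Parse an exported document back into an evaluatable model."""
    if isinstance(source, bytes):
        root = etree.fromstring(source)
    else:
        root = etree.parse(source).getroot()
    ns = {"s": SBML_NS, "m": MATHML_NS}
    species: dict[str, float] = {}
    boundary: dict[str, float] = {}
    for sp in root.findall(".//s:listOfSpecies/s:species", ns):
        target = boundary if sp.get("boundaryCondition") == "true" else species
        target[sp.get("id")] = float(sp.get("initialConcentration"))
    parameters = {
        p.get("id"): float(p.get("value"))
        for p in root.findall(".//s:listOfParameters/s:parameter", ns)
    }
    laws: dict[int, etree._Element] = {}
    stoich: dict[int, dict[str, float]] = {}
    for rxn in root.findall(".//s:listOfReactions/s:reaction", ns):
        rid = int(rxn.get("id")[1:])
        laws[rid] = rxn.find("s:kineticLaw/m:math", ns)
        coefs: dict[str, float] = {}
        for ref in rxn.findall("s:listOfReactants/s:speciesReference", ns):
            coefs[ref.get("species")] = -float(ref.get("stoichiometry"))
        for ref in rxn.findall("s:listOfProducts/s:speciesReference", ns):
            coefs[ref.get("species")] = float(ref.get("stoichiometry"))
        stoich[rid] = coefs
    return SbmlModel(species, boundary, parameters, laws, stoich)
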