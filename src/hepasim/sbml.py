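"""SBML Level 3 export of the whole-body and subcellular ODE systems.

The export is an interchange convenience: the simulator integrates its
own transcription of the rate equations and never executes SBML at run
time.  Documents are built directly as XML (deterministically, with no
timestamps, so export -> import -> export is byte-stable) and carry one
species per state variable, one compartment per organ (or one hepatocyte
compartment), global parameters under their canonical names, unit
definitions, and one reaction per rate law with its kinetic law in
MathML.  :func:`import_sbml` reads a document back and recovers the
parameter values exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from lxml import etree

from .params import ParameterSet
from .pbpk import STATE_FIELDS
from .subcell import SPECIES

__all__ = ["export_sbml", "import_sbml", "validate_sbml"]

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_E = "{%s}" % _SBML_NS

# expression mini-language: str -> <ci>, number -> <cn>,
# tuple ("*"|"/"|"+"|"-", args...) -> <apply>
_OPS = {"*": "times", "/": "divide", "+": "plus", "-": "minus"}


def _math(expr) -> etree._Element:
    math = etree.Element("{%s}math" % _MATHML_NS,
                         nsmap={None: _MATHML_NS})
    math.append(_expr(expr))
    return math


def _expr(expr) -> etree._Element:
    if isinstance(expr, str):
        el = etree.Element("{%s}ci" % _MATHML_NS)
        el.text = f" {expr} "
        return el
    if isinstance(expr, (int, float)):
        el = etree.Element("{%s}cn" % _MATHML_NS)
        el.text = f" {expr} "
        return el
    op, *args = expr
    apply_ = etree.Element("{%s}apply" % _MATHML_NS)
    apply_.append(etree.Element("{%s}%s" % (_MATHML_NS, _OPS[op])))
    for a in args:
        apply_.append(_expr(a))
    return apply_


def _unit_definitions(parent: etree._Element) -> None:
    defs = {
        "per_hour": [("second", -1, 1, 3600)],
        "litre_per_hour": [("litre", 1, 1, 1), ("second", -1, 1, 3600)],
        "mmol": [("mole", 1, -3, 1)],
        "mmol_per_litre": [("mole", 1, -3, 1), ("litre", -1, 1, 1)],
        "per_second": [("second", -1, 1, 1)],
        "mmol_per_litre_second": [("mole", 1, -3, 1), ("litre", -1, 1, 1),
                                  ("second", -1, 1, 1)],
    }
    lod = etree.SubElement(parent, _E + "listOfUnitDefinitions")
    for uid, units in defs.items():
        ud = etree.SubElement(lod, _E + "unitDefinition", id=uid)
        lou = etree.SubElement(ud, _E + "listOfUnits")
        for kind, exp, scale, mult in units:
            etree.SubElement(lou, _E + "unit", kind=kind,
                             exponent=str(exp), scale=str(scale),
                             multiplier=str(mult))


def _document(model_id: str) -> tuple[etree._Element, etree._Element]:
    root = etree.Element(_E + "sbml", nsmap={None: _SBML_NS})
    root.set("level", "3")
    root.set("version", "2")
    model = etree.SubElement(root, _E + "model", id=model_id)
    _unit_definitions(model)
    return root, model


def _add_parameters(model: etree._Element,
                    values: Mapping[str, float]) -> None:
    lop = etree.SubElement(model, _E + "listOfParameters")
    for name, val in values.items():
        etree.SubElement(lop, _E + "parameter", id=name, value=repr(val),
                         constant="true")


def _add_reaction(lor: etree._Element, rid: str, reactants: list[str],
                  products: list[str], law) -> None:
    rx = etree.SubElement(lor, _E + "reaction", id=rid, reversible="false")
    if reactants:
        lo = etree.SubElement(rx, _E + "listOfReactants")
        for s in reactants:
            etree.SubElement(lo, _E + "speciesReference", species=s,
                             stoichiometry="1", constant="true")
    if products:
        lo = etree.SubElement(rx, _E + "listOfProducts")
        for s in products:
            etree.SubElement(lo, _E + "speciesReference", species=s,
                             stoichiometry="1", constant="true")
    kl = etree.SubElement(rx, _E + "kineticLaw")
    kl.append(_math(law))


def _pbpk_document(params: ParameterSet, compound: str,
                   CLmetab: float) -> etree._Element:
    suffix = {"APAP": "", "APAPG": "G", "APAPS": "S"}[compound]

    def p(stem: str) -> str:
        # compound-dependent parameters carry the compound suffix
        dependent = ("Fup", "Kr2p", "Kk2p", "Kl2p", "Rb2p", "Qgfr")
        return f"pbpk_{stem}{suffix if stem in dependent else ''}"

    root, model = _document(f"pbpk_{compound}")
    volumes = {"CGut": "pbpk_VGut", "CLiver": "pbpk_VLiver",
               "CVen": "pbpk_VVen", "CLung": "pbpk_VLung",
               "CArt": "pbpk_VArt", "CKidney": "pbpk_VKidney",
               "CRest": "pbpk_VRest"}
    loc = etree.SubElement(model, _E + "listOfCompartments")
    for state in STATE_FIELDS:
        size = params[volumes[state]] if state in volumes else 1.0
        etree.SubElement(loc, _E + "compartment",
                         id=f"comp_{state}", size=repr(size),
                         spatialDimensions="3", constant="true",
                         units="litre")
    los = etree.SubElement(model, _E + "listOfSpecies")
    for state in STATE_FIELDS:
        etree.SubElement(
            los, _E + "species", id=state, compartment=f"comp_{state}",
            initialAmount="0", hasOnlySubstanceUnits="true",
            boundaryCondition="false", constant="false",
            substanceUnits="mmol")
    pvals = {p(k): params[f"pbpk_{k}{suffix}"
                          if f"pbpk_{k}{suffix}" in params else f"pbpk_{k}"]
             for k in ("QCardiac", "QGut", "QLiver", "QKidney", "QRest",
                       "VArt", "VVen", "VGut", "VLiver", "VKidney", "VLung",
                       "VRest")}
    for stem in ("Fup", "Kr2p", "Kk2p", "Kl2p", "Rb2p", "Qgfr"):
        pvals[p(stem)] = params[f"pbpk_{stem}{suffix}"]
    pvals["pbpk_kGutabs"] = (params["pbpk_kGutabs"]
                             if compound == "APAP" else 0.0)
    pvals["CLmetab"] = CLmetab
    _add_parameters(model, pvals)

    lor = etree.SubElement(model, _E + "listOfReactions")
    _add_reaction(lor, "absorption", ["AGutlumen"], ["CGut"],
                  ("*", "pbpk_kGutabs", "AGutlumen"))
    _add_reaction(lor, "gut_to_liver", ["CGut"], ["CLiver"],
                  ("/", ("*", "pbpk_QGut", "CGut"), "pbpk_VGut"))
    _add_reaction(lor, "liver_to_ven", ["CLiver"], ["CVen"],
                  ("/", ("*", ("+", "pbpk_QLiver", "pbpk_QGut"),
                         "CLiver", p("Rb2p")),
                   ("*", p("Kl2p"), p("Fup"), "pbpk_VLiver")))
    _add_reaction(lor, "liver_metabolism", ["CLiver"], ["CMetabolized"],
                  ("/", ("*", "CLmetab", "CLiver"),
                   ("*", p("Kl2p"), p("Fup"))))
    _add_reaction(lor, "ven_to_lung", ["CVen"], ["CLung"],
                  ("/", ("*", "pbpk_QCardiac", "CVen"), "pbpk_VVen"))
    _add_reaction(lor, "lung_to_art", ["CLung"], ["CArt"],
                  ("/", ("*", "pbpk_QCardiac", "CLung"), "pbpk_VLung"))
    _add_reaction(lor, "art_to_gut", ["CArt"], ["CGut"],
                  ("/", ("*", "pbpk_QGut", "CArt"), "pbpk_VArt"))
    _add_reaction(lor, "art_to_liver", ["CArt"], ["CLiver"],
                  ("/", ("*", "pbpk_QLiver", "CArt"), "pbpk_VArt"))
    _add_reaction(lor, "art_to_kidney", ["CArt"], ["CKidney"],
                  ("/", ("*", "pbpk_QKidney", "CArt"), "pbpk_VArt"))
    _add_reaction(lor, "art_to_rest", ["CArt"], ["CRest"],
                  ("/", ("*", "pbpk_QRest", "CArt"), "pbpk_VArt"))
    _add_reaction(lor, "kidney_to_ven", ["CKidney"], ["CVen"],
                  ("/", ("*", "pbpk_QKidney", "CKidney", p("Rb2p")),
                   ("*", p("Kk2p"), p("Fup"), "pbpk_VKidney")))
    _add_reaction(lor, "filtration", ["CKidney"], ["CTubules"],
                  ("/", ("*", p("Qgfr"), "CKidney"),
                   ("*", p("Kk2p"), "pbpk_VKidney")))
    _add_reaction(lor, "rest_to_ven", ["CRest"], ["CVen"],
                  ("/", ("*", "pbpk_QRest", "CRest", p("Rb2p")),
                   ("*", p("Kr2p"), p("Fup"), "pbpk_VRest")))
    return root


def _subcell_document(params: ParameterSet,
                      zone_scale: float) -> etree._Element:
    root, model = _document("subcell_hepatocyte")
    loc = etree.SubElement(model, _E + "listOfCompartments")
    etree.SubElement(loc, _E + "compartment", id="hepatocyte",
                     size=repr(params["Vol_HEP"] * 1e-15),
                     spatialDimensions="3", constant="true", units="litre")
    los = etree.SubElement(model, _E + "listOfSpecies")
    init = {"GSH": params["sc_GSH0"]}
    for sp in SPECIES:
        etree.SubElement(
            los, _E + "species", id=sp, compartment="hepatocyte",
            initialConcentration=repr(init.get(sp, 0.0)),
            hasOnlySubstanceUnits="false", boundaryCondition="false",
            constant="false", substanceUnits="mmol")
    pvals = {k: params[k] for k in (
        "sc_Vmax_GLUC", "sc_Km_GLUC", "sc_Vmax_SULF", "sc_Km_SULF",
        "sc_Vmax_2E1_APAP", "sc_Km_2E1_APAP", "sc_kNAPQIGSH", "sc_kGsh",
        "sc_GSH0", "sc_GSHmax")}
    pvals["zone_scale"] = zone_scale
    _add_parameters(model, pvals)
    lor = etree.SubElement(model, _E + "listOfReactions")
    _add_reaction(lor, "cyp2e1_oxidation", ["APAP"], ["NAPQI"],
                  ("/", ("*", "zone_scale", "sc_Vmax_2E1_APAP", "APAP"),
                   ("+", "sc_Km_2E1_APAP", "APAP")))
    _add_reaction(lor, "napqi_gsh_conjugation", ["NAPQI", "GSH"],
                  ["NAPQI_GSH"], ("*", "sc_kNAPQIGSH", "NAPQI", "GSH"))
    _add_reaction(lor, "glucuronidation", ["APAP"], ["APAPG"],
                  ("/", ("*", "sc_Vmax_GLUC", "APAP"),
                   ("+", "sc_Km_GLUC", "APAP")))
    _add_reaction(lor, "sulfation", ["APAP"], ["APAPS"],
                  ("/", ("*", "sc_Vmax_SULF", "APAP"),
                   ("+", "sc_Km_SULF", "APAP")))
    _add_reaction(lor, "gsh_synthesis", [], ["GSH"],
                  ("*", "sc_kGsh", ("-", "sc_GSHmax", "GSH")))
    return root


def export_sbml(model: str, params: ParameterSet,
                path: str | Path | None = None, *, compound: str = "APAP",
                CLmetab: float = 0.0, zone_scale: float = 1.0) -> bytes:
    """Serialise the ``"pbpk"`` or ``"subcell"`` model to SBML L3 bytes.

    Writes to ``path`` when given; always returns the document bytes.
    """
    if model == "pbpk":
        root = _pbpk_document(params, compound, CLmetab)
    elif model == "subcell":
        root = _subcell_document(params, zone_scale)
    else:
        raise ValueError(f"unknown model {model!r} (pbpk or subcell)")
    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
    if path is not None:
        Path(path).write_bytes(data)
    return data


def validate_sbml(data: bytes) -> etree._Element:
    """Structural validation; returns the parsed root or raises.

    Checks: well-formed XML in the SBML L3 namespace, a single model,
    unit definitions present, every species referencing a declared
    compartment, and every ``<ci>`` symbol in a kinetic law resolving to
    a species or parameter id.
    """
    root = etree.fromstring(data)
    if root.tag != _E + "sbml" or root.get("level") != "3":
        raise ValueError("not an SBML Level 3 document")
    models = root.findall(_E + "model")
    if len(models) != 1:
        raise ValueError("expected exactly one model element")
    model = models[0]
    if model.find(_E + "listOfUnitDefinitions") is None:
        raise ValueError("unit definitions missing")
    comps = {c.get("id") for c in model.iter(_E + "compartment")}
    species = {s.get("id") for s in model.iter(_E + "species")}
    for s in model.iter(_E + "species"):
        if s.get("compartment") not in comps:
            raise ValueError(f"species {s.get('id')} has unknown compartment")
    pids = {p.get("id") for p in model.iter(_E + "parameter")}
    known = species | pids
    for ci in model.iter("{%s}ci" % _MATHML_NS):
        sym = (ci.text or "").strip()
        if sym not in known:
            raise ValueError(f"kinetic law references unknown symbol {sym!r}")
    return root


def import_sbml(data: bytes | str | Path) -> dict:
    """Parse an exported document back into plain Python structures.

    Returns ``{"model_id", "parameters", "species", "reactions",
    "compartments"}`` with parameter values recovered exactly (they are
    serialised via ``repr``).
    """
    if isinstance(data, (str, Path)) and Path(str(data)).exists():
        data = Path(data).read_bytes()
    root = validate_sbml(data if isinstance(data, bytes)
                         else str(data).encode())
    model = root.find(_E + "model")
    return {
        "model_id": model.get("id"),
        "parameters": {p.get("id"): float(p.get("value"))
                       for p in model.iter(_E + "parameter")},
        "species": [s.get("id") for s in model.iter(_E + "species")],
        "reactions": [r.get("id") for r in model.iter(_E + "reaction")],
        "compartments": {c.get("id"): float(c.get("size"))
                         for c in model.iter(_E + "compartment")},
    }
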