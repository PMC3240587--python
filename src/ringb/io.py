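"""Configuration files, result serialization and SBML export.

Configs are YAML with three blocks: ``model`` (the ModelConfig fields),
``parameters`` (the ParameterSet fields) and an optional free-form ``run``
block used by the command-line interface.  Unknown keys are rejected with
the offending key named.  Parameter sets given in nM are converted to the
internal normalized units once, at load time.

SBML export writes Level 3 Version 2 documents directly (species with
initial concentrations, reactions with kinetic laws, all parameters
global); re-parsing the document must reproduce the variant's stoichiometry
matrix exactly, which is what the tests check.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import fields
from pathlib import Path

import numpy as np
import yaml
from lxml import etree

from . import __version__ as _pkg_version
from .model import (ConfigurationError, ModelConfig, ParameterSet,
                    stoichiometry_matrix, rate_vector, initial_state)

__all__ = ["load_config", "save_config", "export_sbml", "parse_sbml_network",
           "write_provenance"]

_PARAM_FIELDS = {f.name for f in fields(ParameterSet)}
_CONFIG_FIELDS = {f.name for f in fields(ModelConfig)}


def save_config(path, params: ParameterSet, config: ModelConfig,
                run: dict | None = None) -> None:
    doc = {"model": {k: getattr(config, k) for k in _CONFIG_FIELDS},
           "parameters": {k: v for k, v in params.as_dict().items()
                          if v is not None}}
    if run:
        doc["run"] = run
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def load_config(path) -> tuple[ParameterSet, ModelConfig, dict]:
    """Read and validate a YAML config; returns (params, config, run).

    nM parameter sets are converted to normalized units here; the returned
    ModelConfig keeps ``unit_system='normalized'`` so downstream code never
    sees mixed units.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    unknown_blocks = set(doc) - {"model", "parameters", "run"}
    if unknown_blocks:
        raise ConfigurationError(
            f"unknown config block(s): {sorted(unknown_blocks)}")

    cfg_d = doc.get("model", {})
    bad = set(cfg_d) - _CONFIG_FIELDS
    if bad:
        raise ConfigurationError(f"unknown model key(s): {sorted(bad)}")
    config = ModelConfig(**cfg_d)

    par_d = doc.get("parameters", {})
    bad = set(par_d) - _PARAM_FIELDS
    if bad:
        raise ConfigurationError(f"unknown parameter key(s): {sorted(bad)}")
    params = ParameterSet(**par_d)
    params.validate(config)

    if config.unit_system == "nM":
        params = params.to_normalized()
        config = config.replace(unit_system="normalized")
    return params, config, doc.get("run", {}) or {}


def write_provenance(outdir, params: ParameterSet, config: ModelConfig,
                     seed: int | None, command: str) -> Path:
    """Record what produced the files in ``outdir`` (config hash, seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {"parameters": params.as_dict(),
               "model": {k: getattr(config, k) for k in _CONFIG_FIELDS}}
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()
    rec = {"command": command, "seed": seed, "config_sha256": digest,
           "package_version": _pkg_version, **payload}
    p = outdir / "provenance.json"
    p.write_text(json.dumps(rec, indent=1, sort_keys=True))
    return p


# --------------------------------------------------------------------- SBML

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"

#: reactants/products per reaction, mirroring the stoichiometry matrix
_REACTION_SCHEME = {
    "r1": (["B"], ["Bd"]), "r2": (["Bd"], ["B"]),
    "r3": (["R"], ["Rd"]), "r4": (["Rd"], ["R"]),
    "r5": (["B", "R"], ["Z"]), "r6": (["Z"], ["Zub"]),
    "r7": (["Zub"], ["Z"]),
    "r7bind": (["U", "Zub"], ["C7"]), "r7cat": (["C7"], ["Z", "U"]),
    "r8": (["Zub"], ["B", "Ra"]), "r9": (["R"], ["Ru"]),
    "r10": (["Ru"], ["R"]), "r11": (["Ra"], ["R"]),
    "r12": (["H"], ["Hu"]), "r13": (["Hu"], ["H"]),
}

_KINETIC_LAWS_MM = {
    "r1": "k1 * B", "r2": "k2 * u_eff * Bd", "r3": "k3 * R",
    "r4": "k4 * u_eff * Rd", "r5": "k5f * B * R - k5r * Z",
    "r6": "(k6 + k6a * (wZ * Zub + wRa * Ra + wRu * Ru)) * Z",
    "r7": "k7 * USP7_tot * Zub / (KM7 + Zub)",
    "r8": "k8f * Zub - k8r * B * Ra",
    "r9": "(k9 + k9a * (wZ * Zub + wRa * Ra + wRu * Ru)) * R",
    "r10": "k10 * u_eff * Ru", "r11": "k11 * u_eff * Ra",
    "r12": "(cZ * Zub + cRa * Ra + cRu * Ru) * H", "r13": "k13 * Hu",
}


def _mathml(expr: str) -> str:
    """Infix to content MathML by walking the sympy expression tree.

    Covers the operator subset these kinetic laws use (+, *, /, integer
    powers); symbol names are emitted verbatim in <ci> elements.
    """
    import sympy

    def walk(e):
        if e.is_Symbol:
            return f"<ci>{e.name}</ci>"
        if e.is_Number:
            if e.is_Rational and not e.is_Integer:
                return ("<apply><divide/>"
                        f"<cn type=\"integer\">{e.p}</cn>"
                        f"<cn type=\"integer\">{e.q}</cn></apply>")
            return f"<cn>{float(e)}</cn>"
        if e.is_Add:
            return ("<apply><plus/>" +
                    "".join(walk(a) for a in e.args) + "</apply>")
        if e.is_Mul:
            return ("<apply><times/>" +
                    "".join(walk(a) for a in e.args) + "</apply>")
        if e.is_Pow:
            return ("<apply><power/>" + walk(e.base) + walk(e.exp)
                    + "</apply>")
        raise NotImplementedError(f"cannot export term {e!r} to MathML")

    return walk(sympy.sympify(expr.replace("^", "**")))


def export_sbml(params: ParameterSet, config: ModelConfig, path,
                initial: np.ndarray | None = None) -> Path:
    """Write the model as an SBML Level 3 Version 2 document.

    Long-timescale synthesis/degradation is not exported (unsupported);
    request the short-timescale config for SBML output.
    """
    if config.timescale == "long":
        raise NotImplementedError(
            "SBML export supports the short-timescale model only")
    params.validate(config)
    mass_action = config.variant == "mass-action"
    species = config.species
    if initial is None:
        initial = initial_state(
            config, B=params.Bmi1_tot, R=params.R1B_tot, H=params.H2A_tot,
            **({"U": params.USP7_tot} if mass_action else {}))

    E = lambda tag, **kw: etree.SubElement(kw.pop("parent"),
                                           f"{{{_SBML_NS}}}{tag}", **kw)
    root = etree.Element(f"{{{_SBML_NS}}}sbml", level="3", version="2")
    model = E("model", parent=root, id="ring1b_bmi1_h2a")
    lc = E("listOfCompartments", parent=model)
    E("compartment", parent=lc, id="cell", spatialDimensions="3",
      size="1", constant="true")
    ls = E("listOfSpecies", parent=model)
    for i, sp in enumerate(species):
        E("species", parent=ls, id=sp, compartment="cell",
          initialConcentration=repr(float(initial[i])),
          hasOnlySubstanceUnits="false", boundaryCondition="false",
          constant="false")
    lp = E("listOfParameters", parent=model)
    skip = {"k7f", "k7r", "k7cat"} if not mass_action else {"k7", "KM7"}
    for name, v in params.as_dict().items():
        if v is None or name in skip:
            continue
        E("parameter", parent=lp, id=name, value=repr(float(v)),
          constant="true")

    laws = dict(_KINETIC_LAWS_MM)
    if mass_action:
        del laws["r7"]
        laws["r7bind"] = "k7f * U * Zub - k7r * C7"
        laws["r7cat"] = "k7cat * C7"
        u_eff = "U"
    elif config.dub_competition:
        u_eff = "(USP7_tot * KM7 / (KM7 + Zub))"
    else:
        u_eff = "USP7_tot"
    if config.reaction10_saturable:
        laws["r10"] = "k10 * u_eff * Ru / (KM10 + Ru)"
    if not config.feedback_enabled:
        laws["r6"] = "k6 * Z"
        laws["r9"] = "k9 * R"

    lr = E("listOfReactions", parent=model)
    for rname in config.rate_names:
        if rname not in _REACTION_SCHEME:
            continue
        reactants, products = _REACTION_SCHEME[rname]
        rev = rname in ("r5", "r8", "r7bind")
        rx = E("reaction", parent=lr, id=rname,
               reversible="true" if rev else "false")
        lre = E("listOfReactants", parent=rx)
        for sp in reactants:
            E("speciesReference", parent=lre, species=sp, stoichiometry="1",
              constant="true")
        lpr = E("listOfProducts", parent=rx)
        for sp in products:
            E("speciesReference", parent=lpr, species=sp, stoichiometry="1",
              constant="true")
        kl = E("kineticLaw", parent=rx)
        math = etree.SubElement(
            kl, "{http://www.w3.org/1998/Math/MathML}math")
        expr = laws[rname].replace("u_eff", u_eff)
        math.append(_mathml_tree(expr))
    path = Path(path)
    path.write_bytes(etree.tostring(root, pretty_print=True,
                                    xml_declaration=True, encoding="UTF-8"))
    return path


def _mathml_tree(expr: str):
    wrapped = (f'<m xmlns="http://www.w3.org/1998/Math/MathML">'
               f"{_mathml(expr)}</m>")
    return etree.fromstring(wrapped.encode())[0]


def parse_sbml_network(path):
    """Species list and stoichiometry matrix from an SBML file.

    A deliberately small reader used to verify round trips: it understands
    the subset :func:`export_sbml` writes (unit stoichiometries, one
    compartment).
    """
    tree = etree.parse(str(path))
    ns = {"s": _SBML_NS}
    species = [e.get("id") for e in tree.findall(".//s:species", ns)]
    reactions = tree.findall(".//s:reaction", ns)
    S = np.zeros((len(species), len(reactions)))
    names = []
    for j, rx in enumerate(reactions):
        names.append(rx.get("id"))
        for e in rx.findall("s:listOfReactants/s:speciesReference", ns):
            S[species.index(e.get("species")), j] -= float(
                e.get("stoichiometry", 1))
        for e in rx.findall("s:listOfProducts/s:speciesReference", ns):
            S[species.index(e.get("species")), j] += float(
                e.get("stoichiometry", 1))
    return species, names, S
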