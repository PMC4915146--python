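"""SBML Level 3 export and import.

The exported document represents the culture system explicitly for
third-party tools: every integrated quantity (cell concentration, the
intracellular vector, extracellular substrates) is an SBML species driven
by a rate rule; ancillary variables, fluxes, biomass drains and the growth
rate are parameters with assignment rules.  The full native model bundle is
additionally embedded as an annotation so that ``import_sbml(export_sbml(m))``
reconstructs the model losslessly; importing documents produced elsewhere
is not supported.
"""

from __future__ import annotations

import base64
import re

import yaml

from .errors import ModelDefinitionError
from .model import (
    ATP_DIRECT,
    ATP_FADH2,
    ATP_NADH,
    GrowthSpec,
    KineticModel,
    ParameterEntry,
    ParameterSet,
    ProteinBalance,
    RateLaw,
    RHO_PARAM,
    Species,
)

__all__ = ["export_sbml", "import_sbml", "model_to_dict", "model_from_dict"]

_ANNOT_NS = "https://ccmkin.dev/bundle"


def model_to_dict(model: KineticModel) -> dict:
    return {
        "name": model.name,
        "species": [[s.name, s.role, s.display_name] for s in model.species],
        "rate_laws": [
            [r.name, r.kind, r.enzyme, r.gene, r.reversible, r.expression,
             sorted(r.stoichiometry.items())]
            for r in model.rate_laws
        ],
        "ancillary": [[n, e] for n, e in model.ancillary_rules],
        "proteins": [[b.species, b.regulated, b.synthesis] for b in model.protein_balances],
        "drains": list(model.biomass_precursors),
        "parameters": [
            [k, repr(e.value), e.pclass,
             None if e.literature_value is None else repr(e.literature_value),
             repr(e.bounds[0]), repr(e.bounds[1]), e.units, e.positive]
            for k, e in model.parameters.items()
        ],
        "initial": {k: repr(v) for k, v in model.initial_values.items()},
        "growth": [model.growth.mode, model.growth.expression],
        "knocked_out": sorted(model.knocked_out),
    }


def model_from_dict(d: dict) -> KineticModel:
    model = KineticModel(
        species=[Species(*row) for row in d["species"]],
        rate_laws=[
            RateLaw(
                name=row[0], kind=row[1], enzyme=row[2], gene=row[3],
                reversible=row[4], expression=row[5],
                stoichiometry={k: float(v) for k, v in row[6]},
            )
            for row in d["rate_laws"]
        ],
        ancillary_rules=[(n, e) for n, e in d["ancillary"]],
        protein_balances=[ProteinBalance(r[0], r[2], r[1]) for r in d["proteins"]],
        biomass_precursors=list(d["drains"]),
        parameters=ParameterSet(
            {
                row[0]: ParameterEntry(
                    value=float(row[1]), pclass=row[2],
                    literature_value=None if row[3] is None else float(row[3]),
                    bounds=(float(row[4]), float(row[5])), units=row[6],
                    positive=bool(row[7]),
                )
                for row in d["parameters"]
            }
        ),
        initial_state={k: float(v) for k, v in d["initial"].items()},
        growth=GrowthSpec(d["growth"][0], d["growth"][1]),
        name=d["name"],
    )
    ko = d.get("knocked_out") or []
    if ko:
        model.knocked_out = frozenset(ko)
        model.invalidate()
    return model


def _rate_expressions(model: KineticModel) -> dict[str, str]:
    """Infix right-hand-side formula per integrated state, mirroring the
    compiled evaluator (without the negative-overshoot clamp)."""
    rho = RHO_PARAM if RHO_PARAM in model.parameters else "1"
    met = set(model.metabolites)
    syn = {b.species: b.synthesis for b in model.protein_balances}
    drains = set(model.biomass_precursors)
    out = {"X": "(mu - D_dil) * X"}
    for n in model.x1_names:
        if n in met:
            terms = []
            for r in model.rate_laws:
                c = r.stoichiometry.get(n, 0.0)
                if c:
                    terms.append(f"({c}) * v_{r.name}")
            expr = f"{rho} * ({' + '.join(terms)})" if terms else "0"
            if n in drains:
                expr += f" - vBM_{n}"
            out[n] = f"{expr} - mu * {n}"
        else:
            out[n] = f"({syn[n]}) - mu * {n}"
    for j, n in enumerate(model.y_names):
        terms = []
        for r in model.rate_laws:
            c = r.stoichiometry.get(n, 0.0)
            if c:
                terms.append(f"({c}) * v_{r.name}")
        ext = f"X * ({' + '.join(terms)})" if terms else "0"
        out[n] = f"D_dil * (yfeed_{n} - {n}) + {ext}"
    return out


def export_sbml(model: KineticModel, D: float = 0.0, y_feed=None) -> str:
    """Serialize the model (with culture settings) to an SBML L3v2 string."""
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    sm = doc.createModel()
    sm.setId(model.name.replace("-", "_"))
    comp = sm.createCompartment()
    comp.setId("cell")
    comp.setConstant(True)
    comp.setSize(1.0)
    comp.setSpatialDimensions(3)

    def add_species(name, value):
        sp = sm.createSpecies()
        sp.setId(name)
        sp.setCompartment("cell")
        sp.setInitialConcentration(float(value))
        sp.setConstant(False)
        sp.setBoundaryCondition(True)  # all dynamics via rate rules
        sp.setHasOnlySubstanceUnits(False)

    add_species("X", model.initial_values["X"])
    for n in model.x1_names + model.y_names:
        add_species(n, model.initial_values[n])

    def add_param(name, value, constant=True):
        p = sm.createParameter()
        p.setId(name)
        p.setValue(float(value))
        p.setConstant(constant)

    for k, e in model.parameters.items():
        add_param(k, e.value)
    add_param("D_dil", D)
    yf = list(y_feed) if y_feed is not None else [0.0] * len(model.y_names)
    for n, v in zip(model.y_names, yf):
        add_param(f"yfeed_{n}", v)
    for n, _ in model.ancillary_rules:
        add_param(n, 0.0, constant=False)
    for r in model.rate_laws:
        add_param(f"v_{r.name}", 0.0, constant=False)
    for m in model.biomass_precursors:
        add_param(f"vBM_{m}", 0.0, constant=False)
    add_param("mu", 0.0, constant=False)
    add_param("v_ATP", 0.0, constant=False)

    def assignment(target, formula):
        rule = sm.createAssignmentRule()
        rule.setVariable(target)
        ast = libsbml.parseL3Formula(formula.replace("**", "^"))
        if ast is None:
            raise ModelDefinitionError(f"cannot encode formula for {target}: {formula}")
        rule.setMath(ast)

    for n, expr in model.ancillary_rules:
        assignment(n, expr)
    for r in model.rate_laws:
        expr = "0" if (r.gene and r.gene in model.knocked_out) else r.expression
        assignment(f"v_{r.name}", expr)
    if model.biomass_precursors:
        a_glc = "GLCex / (GLCex + K_Pts_GLC)"
        a_ace = f"ACEex / (ACEex + K_Acs_ACE) * (1 - {a_glc})"
        for m in model.biomass_precursors:
            assignment(
                f"vBM_{m}",
                f"(({a_glc}) * k_BM_GLC_{m} + ({a_ace}) * k_BM_ACE_{m}) * {m}",
            )
    if model.growth.mode == "atp":
        nadh = " + ".join(f"v_{n}" for n in ATP_NADH)
        fadh = " + ".join(f"v_{n}" for n in ATP_FADH2)
        direct = " + ".join(f"({c}) * v_{n}" for n, c in ATP_DIRECT.items())
        assignment("v_ATP", f"({nadh}) * PO_NADH + ({fadh}) * PO_FADH2 + {direct}")
        assignment("mu", "k_ATP * v_ATP")
    else:
        assignment("v_ATP", "0")
        assignment("mu", model.growth.expression)
    for target, formula in _rate_expressions(model).items():
        rule = sm.createRateRule()
        rule.setVariable(target)
        ast = libsbml.parseL3Formula(formula.replace("**", "^"))
        if ast is None:
            raise ModelDefinitionError(f"cannot encode rate for {target}: {formula}")
        rule.setMath(ast)

    annot = base64.b64encode(
        yaml.safe_dump(model_to_dict(model), sort_keys=False).encode()
    ).decode()
    sm.setAnnotation(
        f'<ccmkin:bundle xmlns:ccmkin="{_ANNOT_NS}" encoding="base64">{annot}</ccmkin:bundle>'
    )
    return libsbml.writeSBMLToString(doc)


def import_sbml(document: str) -> KineticModel:
    """Reconstruct a model from a document produced by :func:`export_sbml`."""
    import libsbml

    doc = libsbml.readSBMLFromString(document)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise ModelDefinitionError(
            "SBML parse error: " + doc.getErrorLog().toString()
        )
    sm = doc.getModel()
    annot = sm.getAnnotationString() if sm is not None else ""
    match = re.search(r'encoding="base64">([A-Za-z0-9+/=\s]+)<', annot)
    if sm is None or match is None:
        raise ModelDefinitionError(
            "document lacks the embedded bundle annotation; importing "
            "foreign SBML is not supported"
        )
    payload = base64.b64decode("".join(match.group(1).split())).decode()
    d = yaml.safe_load(payload)
    return model_from_dict(d)


def validate_sbml(document: str) -> int:
    """Number of SBML consistency errors (0 for a valid document)."""
    import libsbml

    doc = libsbml.readSBMLFromString(document)
    doc.checkConsistency()
    return doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR)
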