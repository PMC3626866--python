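"""Model and table serialization.

Canonical JSON model schema::

    {
      "metabolites": ["A", "B", ...],
      "reactions": [
        {"id": "R1", "stoich": {"A": 1.0}, "reversible": false, "vmax": 10.0},
        ...
      ],
      "biomass": "Rb",          # optional
      "target": "R3",           # optional
      "units": "nmol/10^6 cells/day"   # optional
    }

``stoich`` maps metabolite id to coefficient (negative = consumed); exchange
reactions simply touch a single internal metabolite.

TSV dialect (one file, two sections)::

    # reactions
    id<TAB>reversible<TAB>vmax<TAB>formula
    R1<TAB>false<TAB>10<TAB> -> A
    R2<TAB>false<TAB><TAB>A -> B
    # designations
    target<TAB>R3
    biomass<TAB>Rb
    units<TAB>mmol/g-DNA/2 days

Formulas use " + "-separated terms with optional numeric coefficients, and
"->" (irreversible) or "<->" (reversible, overridden by the flag column if
both are given).  SBML Level 3 import (requires python-libsbml) drops
boundary species so exchanges become single-ended columns.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .capacity import CapacityTable, ReferenceState
from .exceptions import ParseError, ValidationError
from .model import MetabolicModel

__all__ = [
    "read_model", "write_model", "read_reference_state",
    "write_reference_state", "read_capacities", "write_capacities",
]


# ---------------------------------------------------------------------------
# canonical JSON
# ---------------------------------------------------------------------------

def _model_from_obj(obj: dict, source: str) -> MetabolicModel:
    try:
        metabolites = list(obj["metabolites"])
        reactions = obj["reactions"]
    except (KeyError, TypeError) as err:
        raise ParseError(f"{source}: missing 'metabolites' or 'reactions'") from err
    met_index = {m: i for i, m in enumerate(metabolites)}
    if len(met_index) != len(metabolites):
        raise ValidationError(f"{source}: duplicate metabolite ids")

    rids, reversible, vmax = [], [], {}
    S = np.zeros((len(metabolites), len(reactions)))
    for j, rec in enumerate(reactions):
        try:
            rid = rec["id"]
            stoich = rec["stoich"]
        except (KeyError, TypeError) as err:
            raise ParseError(f"{source}: reaction record {j} lacks id/stoich") from err
        rids.append(rid)
        reversible.append(bool(rec.get("reversible", False)))
        if rec.get("vmax") is not None:
            vmax[rid] = float(rec["vmax"])
        for met, coef in stoich.items():
            if met not in met_index:
                raise ParseError(
                    f"{source}: reaction {rid!r} references unknown metabolite {met!r}")
            S[met_index[met], j] = float(coef)

    return MetabolicModel(
        metabolite_ids=metabolites, reaction_ids=rids, S=S,
        reversible=np.array(reversible, dtype=bool),
        target_id=obj.get("target"), biomass_id=obj.get("biomass"),
        vmax=vmax, units=obj.get("units", ""))


def _model_to_obj(model: MetabolicModel) -> dict:
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        stoich = {model.metabolite_ids[i]: float(model.S[i, j])
                  for i in np.flatnonzero(model.S[:, j])}
        rec = {"id": rid, "stoich": stoich, "reversible": bool(model.reversible[j])}
        if rid in model.vmax:
            rec["vmax"] = float(model.vmax[rid])
        reactions.append(rec)
    obj = {"metabolites": list(model.metabolite_ids), "reactions": reactions}
    if model.biomass_id is not None:
        obj["biomass"] = model.biomass_id
    if model.target_id is not None:
        obj["target"] = model.target_id
    if model.units:
        obj["units"] = model.units
    return obj


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_ARROW = re.compile(r"\s*(<->|->)\s*")
_TERM = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def _parse_side(side: str, sign: float, stoich: dict, source: str) -> None:
    side = side.strip()
    if not side:
        return
    for term in side.split(" + "):
        m = _TERM.match(term)
        if not m:
            raise ParseError(f"{source}: cannot parse formula term {term!r}")
        coef = float(m.group(1)) if m.group(1) else 1.0
        met = m.group(2)
        stoich[met] = stoich.get(met, 0.0) + sign * coef


def _parse_formula(formula: str, source: str) -> tuple[dict, bool]:
    parts = _ARROW.split(formula)
    if len(parts) != 3:
        raise ParseError(f"{source}: formula {formula!r} needs exactly one arrow")
    lhs, arrow, rhs = parts
    stoich: dict[str, float] = {}
    _parse_side(lhs, -1.0, stoich, source)
    _parse_side(rhs, +1.0, stoich, source)
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    return stoich, arrow == "<->"


def _format_formula(stoich: dict[str, float]) -> str:
    def side(items):
        return " + ".join(
            (f"{abs(c):g} {m}" if abs(c) != 1 else m) for m, c in items)
    lhs = side([(m, c) for m, c in stoich.items() if c < 0])
    rhs = side([(m, c) for m, c in stoich.items() if c > 0])
    return f"{lhs} -> {rhs}"


def _model_from_tsv(path: Path) -> MetabolicModel:
    section = None
    reactions = []
    designations = {}
    header = None
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.strip().lower() in ("# reactions", "#reactions"):
            section, header = "reactions", None
            continue
        if line.strip().lower() in ("# designations", "#designations"):
            section = "designations"
            continue
        if section == "reactions":
            fields = line.split("\t")
            if header is None:
                header = fields
                expected = ["id", "reversible", "vmax", "formula"]
                if [h.strip() for h in header] != expected:
                    raise ParseError(
                        f"{path}:{lineno}: reactions header must be {expected}")
                continue
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            rid, rev, vmax, formula = (f.strip() for f in fields)
            stoich, rev_formula = _parse_formula(formula, f"{path}:{lineno}")
            rec = {"id": rid, "stoich": stoich,
                   "reversible": rev.lower() in ("true", "1", "yes") or
                                 (rev == "" and rev_formula)}
            if vmax:
                rec["vmax"] = float(vmax)
            reactions.append(rec)
        elif section == "designations":
            key, _, value = line.partition("\t")
            designations[key.strip()] = value.strip()
        else:
            raise ParseError(f"{path}:{lineno}: content before any section header")
    if not reactions:
        raise ParseError(f"{path}: no reactions found")

    metabolites = []
    seen = set()
    for rec in reactions:
        for met in rec["stoich"]:
            if met not in seen:
                seen.add(met)
                metabolites.append(met)
    obj = {"metabolites": metabolites, "reactions": reactions}
    for key in ("target", "biomass", "units"):
        if designations.get(key):
            obj[key] = designations[key]
    return _model_from_obj(obj, str(path))


def _model_to_tsv(model: MetabolicModel) -> str:
    lines = ["# reactions", "id\treversible\tvmax\tformula"]
    for j, rid in enumerate(model.reaction_ids):
        stoich = {model.metabolite_ids[i]: float(model.S[i, j])
                  for i in np.flatnonzero(model.S[:, j])}
        vmax = f"{model.vmax[rid]:g}" if rid in model.vmax else ""
        rev = "true" if model.reversible[j] else "false"
        lines.append(f"{rid}\t{rev}\t{vmax}\t{_format_formula(stoich)}")
    lines.append("# designations")
    if model.target_id is not None:
        lines.append(f"target\t{model.target_id}")
    if model.biomass_id is not None:
        lines.append(f"biomass\t{model.biomass_id}")
    if model.units:
        lines.append(f"units\t{model.units}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# SBML import
# ---------------------------------------------------------------------------

def _model_from_sbml(path: Path) -> MetabolicModel:
    try:
        import libsbml
    except ImportError as err:  # pragma: no cover
        raise ParseError("SBML import requires python-libsbml") from err
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ParseError(f"{path}: SBML error: {err.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ParseError(f"{path}: no model element")

    boundary = {sp.getId() for sp in sbml_model.getListOfSpecies()
                if sp.getBoundaryCondition()}
    metabolites = [sp.getId() for sp in sbml_model.getListOfSpecies()
                   if sp.getId() not in boundary]

    reactions = []
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            if ref.getSpecies() not in boundary:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            if ref.getSpecies() not in boundary:
                stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        if not stoich:
            continue  # pure-boundary reaction: nothing to balance
        reactions.append({"id": rxn.getId(), "stoich": stoich,
                          "reversible": rxn.getReversible()})
    return _model_from_obj({"metabolites": metabolites, "reactions": reactions},
                           str(path))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_model(path, format: str = "canonical-json") -> MetabolicModel:
    """Read and validate a metabolic model.

    ``format`` is one of ``canonical-json``, ``tsv``, ``sbml``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"model file not found: {path}")
    if format == "canonical-json":
        try:
            obj = json.loads(path.read_text())
        except json.JSONDecodeError as err:
            raise ParseError(f"{path}: invalid JSON: {err}") from err
        return _model_from_obj(obj, str(path))
    if format == "tsv":
        return _model_from_tsv(path)
    if format == "sbml":
        return _model_from_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(model: MetabolicModel, path, format: str = "canonical-json") -> None:
    path = Path(path)
    if format == "canonical-json":
        path.write_text(json.dumps(_model_to_obj(model), indent=1) + "\n")
    elif format == "tsv":
        path.write_text(_model_to_tsv(model))
    else:
        raise ValueError(f"unknown model format {format!r}")


def write_reference_state(ref: ReferenceState, path) -> None:
    """Write SSL/SSU (and measured/biomass metadata) as TSV."""
    frame = pd.DataFrame({
        "reaction_id": ref.reaction_ids,
        "SSL": ref.SSL,
        "SSU": ref.SSU,
        "measured": [ref.measured.get(rid, "") for rid in ref.reaction_ids],
    })
    with open(path, "w") as fh:
        if ref.vbiomass_max is not None:
            fh.write(f"# vbiomass_max\t{ref.vbiomass_max!r}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_reference_state(path) -> ReferenceState:
    path = Path(path)
    vb_max = None
    text = path.read_text().splitlines()
    body_start = 0
    for line in text:
        if line.startswith("# vbiomass_max"):
            vb_max = float(line.split("\t")[1])
            body_start += 1
        else:
            break
    frame = pd.read_csv(path, sep="\t", skiprows=body_start,
                        dtype={"reaction_id": str})
    measured = {row.reaction_id: float(row.measured)
                for row in frame.itertuples()
                if str(row.measured) not in ("", "nan")}
    return ReferenceState(list(frame.reaction_id), frame.SSU.to_numpy(),
                          frame.SSL.to_numpy(), measured=measured,
                          vbiomass_max=vb_max)


def write_capacities(caps: CapacityTable, path) -> None:
    Path(path).write_text(json.dumps(caps.to_json_obj(), indent=1) + "\n")


def read_capacities(path) -> CapacityTable:
    try:
        obj = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise ParseError(f"{path}: invalid JSON: {err}") from err
    return CapacityTable.from_json_obj(obj)
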