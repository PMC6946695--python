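"""Model readers and writers: JSON dialect, TSV tables, SBML L3/fbc.

The JSON dialect mirrors the SBML content one-to-one:

.. code-block:: json

    {
      "id": "toy",
      "compartments": {"c": "cytosol", "e": "extracellular"},
      "metabolites": [
        {"id": "glc_c", "name": "glucose", "compartment": "c",
         "formula": "C6H12O6", "charge": 0, "kegg_id": "C00031"}
      ],
      "reactions": [
        {"id": "HEX1", "stoichiometry": {"glc_c": -1, "g6p_c": 1},
         "lower_bound": 0, "upper_bound": 1000,
         "gpr": "g1 and (g2 or g3)", "ec_numbers": ["2.7.1.1"],
         "subsystems": ["glycolysis"], "kind": "metabolic"}
      ],
      "biomass_reaction_id": "BIOMASS"
    }

The TSV format is a pair of tables ``<stem>.metabolites.tsv`` /
``<stem>.reactions.tsv`` with the same fields; reaction stoichiometry is a
``met:coef;met:coef`` string.  SBML goes through cobra (libsbml) by
conversion to and from a ``cobra.Model``; fbc bounds and GPRs survive the
round trip, reaction kinds are stored in (and recovered from) annotation
notes.  One SBML normalization: an absent metabolite charge comes back as 0
(the fbc charge attribute is not optional in cobra's writer).
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Optional

from .model import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelParseError,
    ModelValidationError,
    Reaction,
    gpr_to_string,
    parse_gpr,
)

logger = logging.getLogger(__name__)

_FORMATS = ("json", "sbml", "tsv")


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    raise ModelParseError(f"cannot infer model format from {path.name!r}")


def load_model(path, fmt: Optional[str] = None) -> MetabolicModel:
    """Load a metabolic model from JSON, SBML or TSV.

    The model is validated (biomass presence is only required when the file
    declares one).  Unparseable GPR strings are stored as empty with a
    logged warning rather than failing the load.
    """
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt != "tsv" and not path.exists():
        raise FileNotFoundError(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    if fmt == "json":
        model = _load_json(path)
    elif fmt == "tsv":
        model = _load_tsv(path)
    else:
        model = _load_sbml(path)
    model.validate(require_biomass=model.biomass_reaction_id is not None)
    return model


def write_model(model: MetabolicModel, path, fmt: Optional[str] = None) -> None:
    """Write a model; ``load_model(write_model(m))`` is the identity.

    Refuses (ModelValidationError) to write a structurally invalid model.
    """
    model.validate(require_biomass=model.biomass_reaction_id is not None)
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt == "json":
        _write_json(model, path)
    elif fmt == "tsv":
        _write_tsv(model, path)
    elif fmt == "sbml":
        _write_sbml(model, path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------


def _parse_gpr_lenient(rule: str, rxn_id: str):
    try:
        return parse_gpr(rule)
    except ModelParseError as exc:
        logger.warning("dropping unparseable GPR on %s: %s", rxn_id, exc)
        return None


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "id": model.id,
        "compartments": dict(model.compartments),
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula,
                "charge": m.charge,
                "kegg_id": m.kegg_id,
            }
            for m in model.metabolites.values()
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": gpr_to_string(r.gpr),
                "ec_numbers": list(r.ec_numbers),
                "subsystems": list(r.subsystems),
                "kind": r.kind,
            }
            for r in model.reactions.values()
        ],
        "biomass_reaction_id": model.biomass_reaction_id,
    }


def model_from_dict(data: dict) -> MetabolicModel:
    try:
        metabolites = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m["compartment"],
                formula=m.get("formula"),
                charge=m.get("charge"),
                kegg_id=m.get("kegg_id"),
            )
            for m in data["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                name=r.get("name", ""),
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=_parse_gpr_lenient(r.get("gpr", ""), r["id"]),
                ec_numbers=list(r.get("ec_numbers", [])),
                subsystems=list(r.get("subsystems", [])),
                kind=r.get("kind", "metabolic"),
            )
            for r in data["reactions"]
        ]
    except KeyError as exc:
        raise ModelParseError(f"missing required model field: {exc}") from exc
    return MetabolicModel(
        model_id=data.get("id", "model"),
        metabolites=metabolites,
        reactions=reactions,
        compartments=data.get("compartments", {}),
        biomass_reaction_id=data.get("biomass_reaction_id"),
    )


def _load_json(path: Path) -> MetabolicModel:
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelParseError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}")
    return model_from_dict(data)


def _write_json(model: MetabolicModel, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------


def _stoich_to_str(stoich: dict[str, float]) -> str:
    return ";".join(f"{m}:{c:g}" for m, c in stoich.items())


def _stoich_from_str(text: str, rxn_id: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" not in part:
            raise ModelParseError(
                f"reaction {rxn_id!r}: bad stoichiometry token {part!r}"
            )
        met, _, coef = part.rpartition(":")
        try:
            out[met] = float(coef)
        except ValueError:
            raise ModelParseError(
                f"reaction {rxn_id!r}: non-numeric coefficient {coef!r}"
            )
    return out


def _tsv_paths(path: Path) -> tuple[Path, Path, Path]:
    stem = path
    if path.name.endswith(".reactions.tsv"):
        stem = path.with_name(path.name[: -len(".reactions.tsv")])
    elif path.name.endswith(".metabolites.tsv"):
        stem = path.with_name(path.name[: -len(".metabolites.tsv")])
    elif path.suffix == ".tsv":
        stem = path.with_suffix("")
    return (
        stem.with_name(stem.name + ".metabolites.tsv"),
        stem.with_name(stem.name + ".reactions.tsv"),
        stem.with_name(stem.name + ".model.json"),
    )


def _load_tsv(path: Path) -> MetabolicModel:
    import pandas as pd

    met_path, rxn_path, meta_path = _tsv_paths(path)
    if not met_path.exists() or not rxn_path.exists():
        raise ModelParseError(
            f"TSV model needs both {met_path.name} and {rxn_path.name}"
        )
    mets = pd.read_csv(met_path, sep="\t", dtype=str).fillna("")
    rxns = pd.read_csv(rxn_path, sep="\t", dtype=str).fillna("")
    metabolites = [
        Metabolite(
            id=row["id"],
            name=row.get("name", ""),
            compartment=row["compartment"],
            formula=row.get("formula") or None,
            charge=int(row["charge"]) if row.get("charge") else None,
            kegg_id=row.get("kegg_id") or None,
        )
        for _, row in mets.iterrows()
    ]
    reactions = [
        Reaction(
            id=row["id"],
            name=row.get("name", ""),
            stoichiometry=_stoich_from_str(row["stoichiometry"], row["id"]),
            lower_bound=float(row["lower_bound"]) if row.get("lower_bound") else -DEFAULT_BOUND,
            upper_bound=float(row["upper_bound"]) if row.get("upper_bound") else DEFAULT_BOUND,
            gpr=_parse_gpr_lenient(row.get("gpr", ""), row["id"]),
            ec_numbers=[e for e in row.get("ec_numbers", "").split(";") if e],
            subsystems=[s for s in row.get("subsystems", "").split(";") if s],
            kind=row.get("kind") or "metabolic",
        )
        for _, row in rxns.iterrows()
    ]
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    return MetabolicModel(
        model_id=meta.get("id", met_path.name.split(".")[0]),
        metabolites=metabolites,
        reactions=reactions,
        compartments=meta.get(
            "compartments", {m.compartment: m.compartment for m in metabolites}
        ),
        biomass_reaction_id=meta.get("biomass_reaction_id"),
    )


def _write_tsv(model: MetabolicModel, path: Path) -> None:
    import pandas as pd

    met_path, rxn_path, meta_path = _tsv_paths(Path(path))
    pd.DataFrame(
        [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "formula": m.formula or "",
                "charge": "" if m.charge is None else m.charge,
                "kegg_id": m.kegg_id or "",
            }
            for m in model.metabolites.values()
        ]
    ).to_csv(met_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": _stoich_to_str(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": gpr_to_string(r.gpr),
                "ec_numbers": ";".join(r.ec_numbers),
                "subsystems": ";".join(r.subsystems),
                "kind": r.kind,
            }
            for r in model.reactions.values()
        ]
    ).to_csv(rxn_path, sep="\t", index=False)
    with open(meta_path, "w") as fh:
        json.dump(
            {
                "id": model.id,
                "compartments": model.compartments,
                "biomass_reaction_id": model.biomass_reaction_id,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")


# ---------------------------------------------------------------------------
# SBML via cobra
# ---------------------------------------------------------------------------


def to_cobra(model: MetabolicModel):
    """Convert to a cobra.Model (fbc bounds, GPR strings, annotations)."""
    import cobra

    cmodel = cobra.Model(model.id)
    cmodel.compartments = dict(model.compartments)
    cmets = {}
    for met in model.metabolites.values():
        cm = cobra.Metabolite(
            met.id,
            name=met.name,
            compartment=met.compartment,
            formula=met.formula,
            charge=met.charge,
        )
        if met.kegg_id:
            cm.annotation["kegg.compound"] = met.kegg_id
        cmets[met.id] = cm
    cmodel.add_metabolites(list(cmets.values()))
    crxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(
            rxn.id,
            name=rxn.name,
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
        )
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for rxn in model.reactions.values():
        cr = cmodel.reactions.get_by_id(rxn.id)
        cr.add_metabolites({cmets[m]: c for m, c in rxn.stoichiometry.items()})
        rule = gpr_to_string(rxn.gpr)
        if rule:
            cr.gene_reaction_rule = rule
        if rxn.ec_numbers:
            cr.annotation["ec-code"] = list(rxn.ec_numbers)
        cr.subsystem = ";".join(rxn.subsystems)
        cr.notes["kind"] = rxn.kind
    if model.biomass_reaction_id:
        cmodel.objective = model.biomass_reaction_id
    return cmodel


def _infer_kind(cr) -> str:
    kind = cr.notes.get("kind")
    if kind:
        return kind
    if len(cr.metabolites) == 1:
        return "exchange" if cr.id.upper().startswith("EX_") else "demand"
    compartments = {m.compartment for m in cr.metabolites}
    if len(compartments) > 1:
        return "transport"
    return "metabolic"


def from_cobra(cmodel) -> MetabolicModel:
    """Convert a cobra.Model into the native representation."""
    metabolites = [
        Metabolite(
            id=cm.id,
            name=cm.name or "",
            compartment=cm.compartment,
            formula=cm.formula or None,
            charge=cm.charge if cm.charge is not None else None,
            kegg_id=(
                cm.annotation.get("kegg.compound")
                if isinstance(cm.annotation.get("kegg.compound"), str)
                else (cm.annotation.get("kegg.compound") or [None])[0]
            )
            if cm.annotation.get("kegg.compound")
            else None,
        )
        for cm in cmodel.metabolites
    ]
    biomass_id = None
    try:
        from cobra.util.solver import linear_reaction_coefficients

        coeffs = linear_reaction_coefficients(cmodel)
        if coeffs:
            biomass_id = next(iter(coeffs)).id
    except Exception:  # objective may be unset/non-linear
        pass
    reactions = []
    for cr in cmodel.reactions:
        ec = cr.annotation.get("ec-code", [])
        if isinstance(ec, str):
            ec = [ec]
        kind = _infer_kind(cr)
        reactions.append(
            Reaction(
                id=cr.id,
                name=cr.name or "",
                stoichiometry={m.id: c for m, c in cr.metabolites.items()},
                lower_bound=float(cr.lower_bound),
                upper_bound=float(cr.upper_bound),
                gpr=_parse_gpr_lenient(cr.gene_reaction_rule, cr.id),
                ec_numbers=list(ec),
                subsystems=[s for s in (cr.subsystem or "").split(";") if s],
                kind=kind,
            )
        )
    compartments = dict(cmodel.compartments)
    for met in metabolites:
        compartments.setdefault(met.compartment, met.compartment)
    model = MetabolicModel(
        model_id=cmodel.id or "model",
        metabolites=metabolites,
        reactions=reactions,
        compartments=compartments,
        biomass_reaction_id=biomass_id,
    )
    if biomass_id and biomass_id in model.reactions:
        model.reactions[biomass_id].kind = "biomass"
    return model


def _load_sbml(path: Path) -> MetabolicModel:
    from cobra.io import read_sbml_model

    return from_cobra(read_sbml_model(str(path)))


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    from cobra.io import write_sbml_model

    write_sbml_model(to_cobra(model), str(path))
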