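"""Biomass-building-block (BBB) production analysis and pathway tallies.

Each biomass precursor (a substrate of the biomass reaction) is probed by
maximizing a transient demand sink on it — per condition and per alternative
active set when a two-condition consistency problem is supplied, or against
a plain (T)FA model otherwise.  Precursors are grouped into the standard
biochemical classes (amino acids, nucleotides, lipids, ...), fold-changes of
maximal production between conditions are computed from a representative
alternative, and paired per-alternative productions feed a two-sided
Wilcoxon signed-rank test per precursor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import DEFAULT_BOUND, MetabolicModel, Reaction
from .remi import RemiProblem
from .thermo import TFASettings, ThermoAnnotation, solve_tfa

logger = logging.getLogger(__name__)

BBB_GROUPS = (
    "carbohydrates",
    "cofactors and vitamins",
    "DNA nucleotides",
    "lipids",
    "minerals",
    "amino acids",
    "RNA nucleotides",
)

#: Compartment-stripped id -> group, for common precursor naming conventions.
DEFAULT_GROUP_MAP: dict[str, str] = {
    **{
        aa: "amino acids"
        for aa in (
            "ala", "arg", "asn", "asp", "cys", "gln", "glu", "gly", "his",
            "ile", "leu", "lys", "met", "phe", "pro", "ser", "thr", "trp",
            "tyr", "val",
            "ala__l", "arg__l", "asn__l", "asp__l", "cys__l", "gln__l",
            "glu__l", "gly__l", "his__l", "ile__l", "leu__l", "lys__l",
            "met__l", "phe__l", "pro__l", "ser__l", "thr__l", "trp__l",
            "tyr__l", "val__l",
        )
    },
    **{n: "RNA nucleotides" for n in ("atp", "gtp", "ctp", "utp")},
    **{n: "DNA nucleotides" for n in ("datp", "dgtp", "dctp", "dttp")},
    **{
        n: "cofactors and vitamins"
        for n in ("nad", "nadh", "nadp", "nadph", "fad", "coa", "thf",
                  "btn", "ribflv", "pydx5p", "thmpp", "amet")
    },
    **{n: "lipids" for n in ("pe160", "pg160", "clpn160", "pa160", "kdo2lipid4")},
    **{n: "carbohydrates" for n in ("glycogen", "udpg", "g6p", "f6p", "murein")},
    **{n: "minerals" for n in ("k", "mg2", "ca2", "fe2", "fe3", "zn2", "cl",
                               "cu2", "mn2", "cobalt2", "so4", "nh4")},
}


@dataclass
class BiomassPrecursor:
    metabolite_id: str
    group: str
    coefficient: float  # stoichiometric coefficient in biomass (negative)


@dataclass
class BBBReport:
    """Per-precursor production table plus group summaries.

    ``table`` columns: precursor, group, production_reference,
    production_perturbed, fold_change (reference/perturbed), p_value,
    flag (ok | denominator-zero | p-unavailable).
    """

    table: pd.DataFrame
    higher_in_reference: int = 0
    higher_in_perturbed: int = 0
    unchanged: int = 0
    group_summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def _base_id(model: MetabolicModel, met_id: str) -> str:
    met = model.metabolites[met_id]
    if met_id.endswith("_" + met.compartment):
        return met_id[: -len(met.compartment) - 1].lower()
    return met_id.lower()


def list_bbbs(
    model: MetabolicModel, group_map: Optional[Mapping[str, str]] = None
) -> list[BiomassPrecursor]:
    """All biomass substrates with their group assignment.

    Looks the compartment-stripped id up in the group map (default table of
    standard biochemical classes); unmapped precursors become
    ``unclassified`` with a warning.
    """
    group_map = {k.lower(): v for k, v in (group_map or DEFAULT_GROUP_MAP).items()}
    biomass = model.biomass_reaction  # raises if absent
    out = []
    for mid, coef in sorted(biomass.stoichiometry.items()):
        if coef >= 0:
            continue
        base = _base_id(model, mid)
        group = group_map.get(base) or group_map.get(mid.lower())
        if group is None:
            logger.warning("biomass precursor %s not in group map; unclassified", mid)
            group = "unclassified"
        out.append(BiomassPrecursor(mid, group, coef))
    return out


def max_bbb_production(
    model: MetabolicModel,
    precursor_id: str,
    thermo: Optional[ThermoAnnotation] = None,
    settings: Optional[TFASettings] = None,
) -> tuple[float, str]:
    """Unconstrained (T)FA maximum of a transient demand on the precursor.

    Adds an irreversible sink ``precursor ->`` with bounds [0, 1000], sets it
    as the objective, solves, and leaves the input model untouched.  Returns
    (flux, status); an infeasible or blocked precursor yields (0.0,
    "blocked") rather than raising.
    """
    if precursor_id not in model.metabolites:
        raise KeyError(f"unknown metabolite {precursor_id!r}")
    probe = model.copy()
    dem_id = f"DM_{precursor_id}"
    while dem_id in probe.reactions:
        dem_id += "_"
    probe.reactions[dem_id] = Reaction(
        id=dem_id,
        stoichiometry={precursor_id: -1.0},
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
        kind="demand",
    )
    sol = solve_tfa(probe, thermo, settings, objective_reaction=dem_id)
    if not sol.ok or sol.objective_value is None:
        return 0.0, "infeasible"
    value = max(sol.objective_value, 0.0)
    if value <= 1e-9:
        return 0.0, "blocked"
    return value, "optimal"


def bbb_production_matrix(
    problem: RemiProblem,
    precursors: list[BiomassPrecursor],
    alternatives: list[list[str]],
) -> dict[str, pd.DataFrame]:
    """Max production per precursor (rows) per alternative (columns), for
    both condition copies of a consistency problem."""
    out = {}
    for condition in ("reference", "perturbed"):
        data = {
            f"alt{k}": [
                problem.max_production(p.metabolite_id, condition, active)
                for p in precursors
            ]
            for k, active in enumerate(alternatives)
        }
        out[condition] = pd.DataFrame(
            data, index=[p.metabolite_id for p in precursors]
        )
    return out


def bbb_fold_changes(
    production_reference: pd.DataFrame,
    production_perturbed: pd.DataFrame,
    precursors: list[BiomassPrecursor],
    representative: int = 0,
    tol: float = 1e-6,
) -> BBBReport:
    """Fold-changes (reference/perturbed) and cross-alternative statistics.

    Fold-changes come from the representative alternative (column index);
    the p-value per precursor is a two-sided Wilcoxon signed-rank test over
    per-alternative paired productions, marked unavailable with fewer than
    two alternatives or all-zero differences.  Swapping the two inputs
    inverts every defined fold-change.
    """
    from scipy.stats import wilcoxon

    if list(production_reference.index) != list(production_perturbed.index):
        raise ValueError("condition tables must share the precursor index")
    n_alts = production_reference.shape[1]
    groups = {p.metabolite_id: p.group for p in precursors}
    rows = []
    higher_ref = higher_pert = unchanged = 0
    for mid in production_reference.index:
        ref = float(production_reference.iloc[:, representative][mid])
        pert = float(production_perturbed.iloc[:, representative][mid])
        if pert > tol:
            fc = ref / pert
            flag = "ok"
        elif ref > tol:
            fc = math.inf
            flag = "denominator-zero"
        else:
            fc = float("nan")
            flag = "denominator-zero"
        if ref > pert + tol:
            higher_ref += 1
        elif pert > ref + tol:
            higher_pert += 1
        else:
            unchanged += 1
        p_value = float("nan")
        if n_alts >= 2:
            a = production_reference.loc[mid].to_numpy(dtype=float)
            b = production_perturbed.loc[mid].to_numpy(dtype=float)
            diffs = a - b
            if np.any(np.abs(diffs) > tol):
                try:
                    p_value = float(wilcoxon(a, b, zero_method="zsplit").pvalue)
                except ValueError:
                    p_value = float("nan")
        else:
            flag = flag if flag != "ok" else "p-unavailable"
        rows.append(
            {
                "precursor": mid,
                "group": groups.get(mid, "unclassified"),
                "production_reference": ref,
                "production_perturbed": pert,
                "fold_change": fc,
                "p_value": p_value,
                "flag": flag,
            }
        )
    table = pd.DataFrame(rows)
    group_summary = (
        table.groupby("group")
        .agg(
            n=("precursor", "count"),
            mean_reference=("production_reference", "mean"),
            mean_perturbed=("production_perturbed", "mean"),
        )
        .reset_index()
    )
    return BBBReport(
        table=table,
        higher_in_reference=higher_ref,
        higher_in_perturbed=higher_pert,
        unchanged=unchanged,
        group_summary=group_summary,
    )


def tally_deregulated_pathways(
    common_items: Mapping[str, str] | list[str],
    pathway_annotation: Mapping[str, list[str]],
) -> list[tuple[str, int]]:
    """Count deregulated reactions+metabolites per pathway, ranked descending.

    ``common_items`` are candidate ids (``gene:<rxn>`` / ``met:<met>``) or
    bare entity ids; the annotation maps entity ids to pathway id lists.
    Items in several pathways count once in each; unannotated items count
    under ``unannotated``.  Ties are broken by pathway id.
    """
    counts: dict[str, int] = {}
    for item in common_items:
        entity = item.split(":", 1)[1] if ":" in item else item
        pathways = pathway_annotation.get(entity)
        if not pathways:
            counts["unannotated"] = counts.get("unannotated", 0) + 1
            continue
        for pw in pathways:
            counts[pw] = counts.get(pw, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def load_pathway_annotation(path) -> dict[str, list[str]]:
    """TSV with columns id, pathway_id (pathway_name optional)."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["id"]), []).append(str(row["pathway_id"]))
    return out
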