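"""Network decomposition, blocked-reaction detection and MILP gap-filling.

A *blocked* reaction cannot carry flux under any exchange configuration —
detected here by flux variability analysis at objective fraction 0 with all
exchanges opened.  Blocked reactions typically sit in small connectivity
islands: the bipartite reaction–metabolite graph (with currency metabolites
removed, since ATP/NAD(H)/water edges join everything to everything)
decomposes into one main component and isolated fragments.

Gap-filling restores connectivity: given a universal reaction database, a
MILP selects the minimal number of database reactions whose addition lets a
target reaction (or a demand on a target metabolite) carry at least
``min_flux``.  Minimality is certified by MILP optimality, and equal-size
alternative sets are enumerated with integer cuts.  Blocked targets are
prioritized by omics evidence: differentially expressed genes in their GPRs
and measured exometabolites among their participants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

from .lp import LinearProblem
from .model import DEFAULT_BOUND, MetabolicModel, Reaction
from .omics import OmicsData
from .thermo import bwd, flux_variability, fwd

logger = logging.getLogger(__name__)

#: Currency metabolites removed before graph decomposition (matched on the
#: compartment-stripped id, case-insensitive).  Never used in flux math.
DEFAULT_CURRENCY_METABOLITES = frozenset(
    {
        "atp", "adp", "amp", "nad", "nadh", "nadp", "nadph",
        "h", "h2o", "pi", "ppi", "co2", "coa",
    }
)

BLOCKED_TOL = 1e-6


@dataclass
class NetworkComponent:
    component_id: int
    reaction_ids: list[str]
    metabolite_ids: list[str]
    is_main: bool = False

    @property
    def size(self) -> int:
        return len(self.reaction_ids)


@dataclass
class GapfillTask:
    """One gap-filling problem: unblock a reaction or produce a metabolite."""

    target: str
    target_type: str  # "reaction" | "metabolite"
    min_flux: float = 1e-3  # epsilon_gf
    max_alternatives: int = 10
    omics_evidence: list[str] = field(default_factory=list)
    score: int = 0
    gene_hits: int = 0
    metabolite_hits: int = 0
    member_reactions: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.min_flux <= 0:
            raise ValueError("min_flux must be > 0")


@dataclass
class GapfillSolution:
    feasible: bool
    added_reaction_ids: list[str] = field(default_factory=list)
    size: int = 0
    alternative_sets: list[list[str]] = field(default_factory=list)
    genes_suggested: set[str] = field(default_factory=set)
    added_reactions: list[Reaction] = field(default_factory=list)
    added_metabolites: list = field(default_factory=list)


def _base_id(model: MetabolicModel, met_id: str) -> str:
    met = model.metabolites[met_id]
    if met_id.endswith("_" + met.compartment):
        return met_id[: -len(met.compartment) - 1].lower()
    return met_id.lower()


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------


def decompose_network(
    model: MetabolicModel,
    currency_metabolites: Optional[Iterable[str]] = None,
) -> list[NetworkComponent]:
    """Connected components of the reaction–metabolite bipartite graph.

    Currency metabolites (by compartment-stripped id) are dropped before
    computing components; components are ordered by reaction count
    descending, then by smallest reaction id, and the largest is ``is_main``.
    The components partition the reaction set.
    """
    currency = frozenset(
        c.lower() for c in (currency_metabolites or DEFAULT_CURRENCY_METABOLITES)
    )
    graph = nx.Graph()
    for rid in model.reactions:
        graph.add_node(("r", rid))
    for rid, rxn in model.reactions.items():
        for mid in rxn.stoichiometry:
            if _base_id(model, mid) in currency:
                continue
            graph.add_node(("m", mid))
            graph.add_edge(("r", rid), ("m", mid))
    components = []
    for nodes in nx.connected_components(graph):
        rxns = sorted(n[1] for n in nodes if n[0] == "r")
        mets = sorted(n[1] for n in nodes if n[0] == "m")
        if rxns or mets:
            components.append((rxns, mets))
    components.sort(key=lambda c: (-len(c[0]), c[0][0] if c[0] else ""))
    out = [
        NetworkComponent(i, rxns, mets, is_main=(i == 0))
        for i, (rxns, mets) in enumerate(components)
    ]
    return out


# ---------------------------------------------------------------------------
# Blocked reactions
# ---------------------------------------------------------------------------


def _open_exchanges(model: MetabolicModel) -> MetabolicModel:
    probe = model.copy()
    for rxn in probe.reactions.values():
        if rxn.kind == "exchange":
            rxn.lower_bound = -DEFAULT_BOUND
            rxn.upper_bound = DEFAULT_BOUND
    return probe


def find_blocked_reactions(
    model: MetabolicModel, tol: float = BLOCKED_TOL
) -> set[str]:
    """Reactions that cannot carry flux under any exchange configuration.

    All exchanges are opened to the default bounds for the probe; a reaction
    is blocked iff its FVA range at objective fraction 0 is (0, 0).  The
    result is independent of the objective and of reaction ordering.
    """
    probe = _open_exchanges(model)
    ranges = flux_variability(probe, objective_fraction=0.0)
    return {
        rid
        for rid, (lo, hi) in ranges.items()
        if abs(lo) <= tol and abs(hi) <= tol
    }


def prioritize_blocked(
    model: MetabolicModel,
    blocked: set[str],
    omics: OmicsData,
    fold_threshold: float = 2.0,
    fdr_cutoff: float = 0.05,
    min_flux: float = 1e-3,
) -> list[GapfillTask]:
    """Rank blocked pathways by omics support.

    Blocked reactions are grouped into maximal connected chains (components
    of the bipartite graph restricted to blocked reactions); each group is
    scored by the number of significantly DE genes in its GPRs plus the
    number of measured metabolites among its participants.  Only groups with
    score > 0 become tasks, ordered by score descending then target id.
    """
    if not blocked:
        return []
    de_genes = set(omics.significant_genes(fold_threshold, fdr_cutoff))
    measured = set(omics.significant_metabolites())
    measured_bases = {m.lower() for m in measured}

    sub = nx.Graph()
    for rid in blocked:
        sub.add_node(("r", rid))
        for mid in model.reactions[rid].stoichiometry:
            sub.add_node(("m", mid))
            sub.add_edge(("r", rid), ("m", mid))
    tasks = []
    for nodes in nx.connected_components(sub):
        rxns = sorted(n[1] for n in nodes if n[0] == "r")
        if not rxns:
            continue
        mets = sorted(n[1] for n in nodes if n[0] == "m")
        genes_hit = set()
        for rid in rxns:
            genes_hit |= model.reactions[rid].genes & de_genes
        mets_hit = {
            mid
            for mid in mets
            if mid in measured
            or _base_id(model, mid) in measured_bases
        }
        score = len(genes_hit) + len(mets_hit)
        if score == 0:
            continue
        tasks.append(
            GapfillTask(
                target=rxns[0],
                target_type="reaction",
                min_flux=min_flux,
                omics_evidence=sorted(genes_hit) + sorted(mets_hit),
                score=score,
                gene_hits=len(genes_hit),
                metabolite_hits=len(mets_hit),
                member_reactions=rxns,
            )
        )
    tasks.sort(key=lambda t: (-t.score, t.target))
    return tasks


# ---------------------------------------------------------------------------
# Gap-filling MILP
# ---------------------------------------------------------------------------


def _build_gapfill_problem(
    model: MetabolicModel,
    universal_db: MetabolicModel,
    demand_metabolite: Optional[str] = None,
) -> tuple[LinearProblem, list[str]]:
    """Merged steady-state problem: model reactions plus indicator-gated db
    reactions; optionally a demand sink ``dem[mid]`` on one metabolite."""
    problem = LinearProblem("gapfill")
    candidates = [rid for rid in universal_db.reactions if rid not in model.reactions]
    # flux variables
    probe = _open_exchanges(model)
    for rid, rxn in probe.reactions.items():
        problem.add_variable(
            fwd(rid), max(rxn.lower_bound, 0.0), max(rxn.upper_bound, 0.0)
        )
        problem.add_variable(
            bwd(rid), max(-rxn.upper_bound, 0.0), max(-rxn.lower_bound, 0.0)
        )
    # db candidates are assumed relaxed (lb <= 0 <= ub) so the indicator can
    # switch them off entirely
    for rid in candidates:
        rxn = universal_db.reactions[rid]
        problem.add_variable(fwd(rid), 0.0, max(rxn.upper_bound, 0.0))
        problem.add_variable(bwd(rid), 0.0, max(-rxn.lower_bound, 0.0))
        y = problem.add_variable(f"y[{rid}]", binary=True)
        problem.add_constraint(
            {fwd(rid): 1.0, y: -max(rxn.upper_bound, 0.0)}, -math.inf, 0.0
        )
        problem.add_constraint(
            {bwd(rid): 1.0, y: -max(-rxn.lower_bound, 0.0)}, -math.inf, 0.0
        )
    if demand_metabolite is not None:
        problem.add_variable(f"dem[{demand_metabolite}]", 0.0, DEFAULT_BOUND)
    # steady state over the union metabolite namespace
    all_mets = set(probe.metabolites) | {
        mid for rid in candidates for mid in universal_db.reactions[rid].stoichiometry
    }
    for mid in sorted(all_mets):
        row: dict[str, float] = {}
        for rid, rxn in probe.reactions.items():
            coef = rxn.stoichiometry.get(mid)
            if coef:
                row[fwd(rid)] = coef
                row[bwd(rid)] = -coef
        for rid in candidates:
            coef = universal_db.reactions[rid].stoichiometry.get(mid)
            if coef:
                row[fwd(rid)] = row.get(fwd(rid), 0.0) + coef
                row[bwd(rid)] = row.get(bwd(rid), 0.0) - coef
        if mid == demand_metabolite:
            row[f"dem[{mid}]"] = -1.0
        if row:
            problem.add_constraint(row, 0.0, 0.0)
    return problem, candidates


def _solve_gapfill_direction(
    problem: LinearProblem,
    candidates: list[str],
    activation_row: dict[str, float],
    min_flux: float,
    max_alternatives: int,
) -> Optional[list[list[str]]]:
    """Minimal indicator sets for one activation direction; None if infeasible."""
    act = problem.add_constraint(activation_row, min_flux, math.inf)
    problem.set_objective({f"y[{rid}]": 1.0 for rid in candidates}, sense="min")
    sol = problem.solve()
    if not sol.ok:
        problem.remove_constraint(act)
        return None
    size = round(sol.objective)
    chosen = [rid for rid in candidates if sol.values[f"y[{rid}]"] > 0.5]
    sets = [sorted(chosen)]
    cuts = []
    fix = problem.add_constraint(
        {f"y[{rid}]": 1.0 for rid in candidates}, size, size
    )
    cuts.append(fix)
    while len(sets) < max_alternatives:
        cuts.append(
            problem.add_constraint(
                {f"y[{rid}]": 1.0 for rid in sets[-1]}, -math.inf, size - 1
            )
        )
        sol = problem.solve()
        if not sol.ok:
            break
        sets.append(
            sorted(rid for rid in candidates if sol.values[f"y[{rid}]"] > 0.5)
        )
    for row in cuts:
        problem.remove_constraint(row)
    problem.remove_constraint(act)
    return sets


def gapfill(
    model: MetabolicModel,
    universal_db: MetabolicModel,
    task: GapfillTask,
) -> GapfillSolution:
    """Minimal-addition gap-filling with alternative-set enumeration.

    Minimizes the number of database reactions added so that the target
    reaction carries at least ``min_flux`` (forward, or backward when the
    target is reversible — the cheaper direction wins), or so that a demand
    on the target metabolite can be satisfied.  Equal-size alternatives are
    enumerated via integer cuts.  Returns an infeasible
    :class:`GapfillSolution` when no addition within the database helps.
    """
    demand = task.target if task.target_type == "metabolite" else None
    if demand is not None and demand not in model.metabolites:
        if not any(
            demand in universal_db.reactions[rid].stoichiometry
            for rid in universal_db.reactions
        ):
            raise KeyError(f"target metabolite {task.target!r} not found")
    problem, candidates = _build_gapfill_problem(model, universal_db, demand)
    rows: list[dict[str, float]] = []
    if task.target_type == "reaction":
        source = model.reactions.get(task.target) or universal_db.reactions.get(
            task.target
        )
        if source is None:
            raise KeyError(f"target reaction {task.target!r} not found")
        if source.upper_bound > 0:
            rows.append({fwd(task.target): 1.0})
        if source.lower_bound < 0:
            rows.append({bwd(task.target): 1.0})
    else:
        rows.append({f"dem[{demand}]": 1.0})

    best: Optional[list[list[str]]] = None
    for activation in rows:
        sets = _solve_gapfill_direction(
            problem, candidates, activation, task.min_flux, task.max_alternatives
        )
        if sets is None:
            continue
        if best is None or len(sets[0]) < len(best[0]):
            best = sets
    if best is None:
        return GapfillSolution(feasible=False)
    added = best[0]
    genes: set[str] = set()
    for rid in added:
        genes |= universal_db.reactions[rid].genes
    new_mets = []
    met_ids = {
        mid
        for rid in added
        for mid in universal_db.reactions[rid].stoichiometry
        if mid not in model.metabolites
    }
    for mid in sorted(met_ids):
        new_mets.append(universal_db.metabolites[mid])
    return GapfillSolution(
        feasible=True,
        added_reaction_ids=list(added),
        size=len(added),
        alternative_sets=best,
        genes_suggested=genes,
        added_reactions=[universal_db.reactions[rid] for rid in added],
        added_metabolites=new_mets,
    )


def apply_gapfill(model: MetabolicModel, solution: GapfillSolution) -> MetabolicModel:
    """Return a copy of the model with the gap-fill reactions (and any new
    metabolites) added.  Id collisions are suffix-renamed with a logged
    mapping.  An infeasible or empty solution returns the model unchanged."""
    out = model.copy()
    if not solution.feasible or not solution.added_reactions:
        return out
    for met in solution.added_metabolites:
        if met.id not in out.metabolites:
            out.metabolites[met.id] = met
            out.compartments.setdefault(met.compartment, met.compartment)
    import copy as _copy

    for rxn in solution.added_reactions:
        new = _copy.deepcopy(rxn)
        if new.id in out.reactions:
            renamed = new.id + "_gf"
            k = 1
            while renamed in out.reactions:
                k += 1
                renamed = f"{new.id}_gf{k}"
            logger.warning("gap-fill id collision: %s renamed to %s", new.id, renamed)
            new.id = renamed
        out.reactions[new.id] = new
    out.validate(require_biomass=out.biomass_reaction_id is not None)
    return out
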