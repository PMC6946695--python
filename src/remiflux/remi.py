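"""Two-condition consistency maximization between omics ratios and fluxes.

The integration couples two copies of the same metabolic model — a
*reference* and a *perturbed* condition — in one MILP.  Each copy carries
split fluxes (v = f - b, f,b >= 0), steady state, bounds and (optionally)
thermodynamic direction coupling.  Omics measurements become *candidate
constraints*, each guarded by a binary indicator z:

* an up-regulated reaction r (expression ratio rho >= theta) demands
  ``activity_pert(r) >= min(rho, rho_max) * activity_ref(r)`` with
  ``activity_ref(r) >= eps``, where activity is f + b (total turnover);
* a down-regulated reaction demands the mirror image;
* an up-regulated extracellular metabolite m demands higher *production*
  in the perturbed copy, where production is the total producing-side
  turnover sum(|s_mr| * producing half-flux) — not net exchange, since a
  secreted metabolite may simultaneously be consumed;
* down-regulated metabolites mirror.

The objective maximizes the number of simultaneously satisfiable candidate
constraints.  Two scores summarize the outcome: TMCS, the number of
candidates the data offers, and MCS <= TMCS, the size of the largest
consistent subset.  Alternative optimal active sets are enumerated with
integer cuts, and per-condition growth is a post-hoc biomass maximization
with the indicators pinned to an active set.

Variants: ``tgex`` uses gene expression only, ``tm`` metabolite abundances
only, ``tgexm`` both; all three apply thermodynamic constraints when an
annotation is supplied ("T").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .lp import LinearProblem
from .model import DEFAULT_BOUND, FluxSolution, MetabolicModel, evaluate_gpr
from .omics import OmicsData
from .thermo import (
    TFASettings,
    ThermoAnnotation,
    add_flux_variables,
    add_thermo_constraints,
    bwd,
    fwd,
)

logger = logging.getLogger(__name__)

REF = "R:"
PERT = "P:"

VARIANTS = ("tgex", "tm", "tgexm")


def gene_candidate_id(reaction_id: str) -> str:
    return f"gene:{reaction_id}"


def metabolite_candidate_id(met_id: str) -> str:
    return f"met:{met_id}"


def candidate_source(candidate_id: str) -> str:
    """'gene' or 'metabolite' from a candidate id."""
    return "gene" if candidate_id.startswith("gene:") else "metabolite"


@dataclass
class ReactionRegulation:
    """A reaction-level expression constraint candidate."""

    reaction_id: str
    ratio: float  # perturbed/reference aggregate expression
    direction: str  # "up" | "down"
    source_genes: list[str] = field(default_factory=list)


@dataclass
class RemiSettings:
    variant: str = "tgexm"
    fold_threshold: float = 2.0  # theta
    min_activity: float = 1e-3  # eps
    ratio_cap: float = 100.0  # rho_max
    growth_floor: float = 0.0  # gamma, fraction of per-condition TFA max
    solver_time_limit: Optional[float] = None
    max_alternatives: int = 40
    mip_gap: float = 1e-6
    fdr_cutoff: float = 0.05

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if not (0 <= self.growth_floor < 1):
            raise ValueError("growth_floor must be in [0, 1)")
        if self.min_activity <= 0:
            raise ValueError("min_activity must be > 0")


@dataclass
class ConsistencyResult:
    status: str
    tmcs: int
    mcs: int
    active_set: list[str] = field(default_factory=list)
    alternatives: list[list[str]] = field(default_factory=list)
    growth_reference: Optional[float] = None
    growth_perturbed: Optional[float] = None
    tmcs_gene_level: int = 0  # distinct source genes + metabolites tally


# ---------------------------------------------------------------------------
# Expression -> reaction regulation
# ---------------------------------------------------------------------------


def map_expression_to_reactions(
    model: MetabolicModel,
    omics: OmicsData,
    fold_threshold: float = 2.0,
    fdr_cutoff: float = 0.05,
) -> list[ReactionRegulation]:
    """Aggregate significant per-gene ratios onto reactions through GPRs.

    Only genes passing FDR < cutoff and |log2FC| >= log2(theta) enter.  The
    per-condition reaction expression follows the GPR with AND = min and
    OR = max over genes with data (reference expression of every included
    gene is normalized to 1, perturbed to its ratio); the reaction ratio is
    their quotient.  A regulation is emitted only when the aggregate ratio
    clears theta (up) or 1/theta (down).  Reactions with empty GPRs are
    skipped.
    """
    significant = omics.significant_genes(fold_threshold, fdr_cutoff)
    if not significant:
        return []
    ref_values = {gid: 1.0 for gid in significant}
    pert_values = {gid: rec.ratio for gid, rec in significant.items()}
    out: list[ReactionRegulation] = []
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        if rxn.gpr is None:
            continue
        used = rxn.genes & set(significant)
        if not used:
            continue
        ref_agg = evaluate_gpr(rxn.gpr, ref_values)
        pert_agg = evaluate_gpr(rxn.gpr, pert_values)
        if not ref_agg or pert_agg is None:
            continue
        ratio = pert_agg / ref_agg
        if ratio >= fold_threshold:
            out.append(ReactionRegulation(rid, ratio, "up", sorted(used)))
        elif ratio <= 1.0 / fold_threshold:
            out.append(ReactionRegulation(rid, ratio, "down", sorted(used)))
    return out


# ---------------------------------------------------------------------------
# Problem construction
# ---------------------------------------------------------------------------


@dataclass
class _Candidate:
    candidate_id: str
    kind: str  # "reaction" | "metabolite"
    direction: str  # "up" | "down"
    ratio: float
    target: str  # reaction id or metabolite id
    source_genes: list[str] = field(default_factory=list)


class RemiProblem:
    """A built two-condition MILP handle.

    Use :func:`build_remi_problem`; then :meth:`solve_mcs`,
    :meth:`enumerate_alternatives`, :meth:`condition_growth` and
    :meth:`max_production`.
    """

    def __init__(
        self,
        model: MetabolicModel,
        settings: RemiSettings,
        thermo: Optional[ThermoAnnotation],
        tfa_settings: TFASettings,
    ):
        self.model = model
        self.settings = settings
        self.thermo = thermo
        self.tfa_settings = tfa_settings
        self.problem = LinearProblem(f"remi:{model.id}")
        self.candidates: dict[str, _Candidate] = {}
        self._sum_row: Optional[int] = None
        self._demand_metabolites: set[str] = set()

    # -- bookkeeping --------------------------------------------------------

    @property
    def tmcs(self) -> int:
        return len(self.candidates)

    @property
    def tmcs_gene_level(self) -> int:
        """Alternative tally: distinct source genes plus metabolite candidates."""
        genes: set[str] = set()
        mets = 0
        for cand in self.candidates.values():
            if cand.kind == "reaction":
                genes.update(cand.source_genes)
            else:
                mets += 1
        return len(genes) + mets

    def _zvar(self, candidate_id: str) -> str:
        return f"z[{candidate_id}]"

    def _activity(self, rid: str, prefix: str) -> dict[str, float]:
        return {fwd(rid, prefix): 1.0, bwd(rid, prefix): 1.0}

    def _activity_ub(self, rid: str, prefix: str) -> float:
        rxn = self.model.reactions[rid]
        return max(rxn.upper_bound, 0.0) + max(-rxn.lower_bound, 0.0)

    # -- construction helpers (called by build_remi_problem) ---------------

    def _add_condition_copies(self) -> None:
        for prefix in (REF, PERT):
            add_flux_variables(self.problem, self.model, prefix)
            if self.thermo is not None and not self.thermo.is_empty():
                add_thermo_constraints(
                    self.problem, self.model, self.thermo, self.tfa_settings, prefix
                )
        # closed demand sinks for biomass precursors (opened transiently for
        # production queries); they join the balance rows via fresh rows:
        # dem - contribution == handled by adding dem into a duplicate of the
        # balance row is unnecessary because sinks are created inside
        # add_flux_variables only for the model's reactions.  Instead sinks
        # are modeled as extra variables added to the stored balance rows at
        # build time:
        if self.model.biomass_reaction_id:
            precursors = [
                mid
                for mid, coef in self.model.biomass_reaction.stoichiometry.items()
                if coef < 0
            ]
            for prefix in (REF, PERT):
                for mid in precursors:
                    name = f"{prefix}dem[{mid}]"
                    self.problem.add_variable(name, 0.0, 0.0)
                    self._patch_balance_row(mid, prefix, name)
            self._demand_metabolites = set(precursors)

    def _patch_balance_row(self, mid: str, prefix: str, dem_var: str) -> None:
        """Insert a sink variable into the metabolite's steady-state row."""
        want = {}
        for rid, rxn in self.model.reactions.items():
            coef = rxn.stoichiometry.get(mid)
            if coef:
                want[fwd(rid, prefix)] = coef
                want[bwd(rid, prefix)] = -coef
        for i, (coeffs, lb, ub) in enumerate(self.problem._rows):
            if lb == 0.0 and ub == 0.0 and coeffs == want:
                coeffs[dem_var] = -1.0
                return
        raise RuntimeError(f"balance row for {mid!r} ({prefix}) not found")

    def _add_reaction_candidate(self, reg: ReactionRegulation) -> None:
        cid = gene_candidate_id(reg.reaction_id)
        if cid in self.candidates:
            return
        s = self.settings
        rho = min(max(reg.ratio, 1.0 / s.ratio_cap), s.ratio_cap)
        z = self.problem.add_variable(self._zvar(cid), binary=True)
        rid = reg.reaction_id
        if reg.direction == "up":
            factor, donor, receiver = rho, REF, PERT
        else:
            factor, donor, receiver = 1.0 / rho, PERT, REF
        # receiver activity >= factor * donor activity  when z = 1
        big_m = factor * self._activity_ub(rid, donor) + 1.0
        row = {}
        for var, coef in self._activity(rid, receiver).items():
            row[var] = coef
        for var, coef in self._activity(rid, donor).items():
            row[var] = row.get(var, 0.0) - factor * coef
        row[z] = -big_m
        self.problem.add_constraint(row, -big_m, math.inf)
        # donor activity >= eps when z = 1
        row2 = dict(self._activity(rid, donor))
        row2[z] = -s.min_activity
        self.problem.add_constraint(row2, 0.0, math.inf)
        self.candidates[cid] = _Candidate(
            cid, "reaction", reg.direction, reg.ratio, rid, reg.source_genes
        )

    def _production_terms(self, mid: str, prefix: str) -> dict[str, float]:
        """Total producing-side turnover of a metabolite in one condition."""
        row: dict[str, float] = {}
        for rid, rxn in self.model.reactions.items():
            if rxn.kind == "exchange":
                continue  # the boundary itself never "produces"
            coef = rxn.stoichiometry.get(mid)
            if not coef:
                continue
            if coef > 0:
                row[fwd(rid, prefix)] = row.get(fwd(rid, prefix), 0.0) + coef
            else:
                row[bwd(rid, prefix)] = row.get(bwd(rid, prefix), 0.0) - coef
        return row

    def _production_ub(self, terms: dict[str, float]) -> float:
        total = 0.0
        for var, coef in terms.items():
            _, ub = self.problem.get_bounds(var)
            total += coef * ub
        return total

    def _add_metabolite_candidate(self, mid: str, ratio: float) -> None:
        cid = metabolite_candidate_id(mid)
        if cid in self.candidates or mid not in self.model.metabolites:
            return
        s = self.settings
        ref_terms = self._production_terms(mid, REF)
        pert_terms = self._production_terms(mid, PERT)
        if not ref_terms or not pert_terms:
            logger.warning("metabolite %s has no producing reactions; skipped", mid)
            return
        rho = min(max(ratio, 1.0 / s.ratio_cap), s.ratio_cap)
        direction = "up" if ratio >= 1.0 else "down"
        if direction == "up":
            factor, donor_terms, receiver_terms = rho, ref_terms, pert_terms
        else:
            factor, donor_terms, receiver_terms = 1.0 / rho, pert_terms, ref_terms
        z = self.problem.add_variable(self._zvar(cid), binary=True)
        big_m = factor * self._production_ub(donor_terms) + 1.0
        row = dict(receiver_terms)
        for var, coef in donor_terms.items():
            row[var] = row.get(var, 0.0) - factor * coef
        row[z] = -big_m
        self.problem.add_constraint(row, -big_m, math.inf)
        row2 = dict(donor_terms)
        row2[z] = -s.min_activity
        self.problem.add_constraint(row2, 0.0, math.inf)
        self.candidates[cid] = _Candidate(cid, "metabolite", direction, ratio, mid)

    def _add_growth_floor(self) -> None:
        gamma = self.settings.growth_floor
        if gamma <= 0 or not self.model.biomass_reaction_id:
            return
        from .thermo import solve_tfa

        base = solve_tfa(
            self.model, self.thermo, self.tfa_settings, self.model.biomass_reaction_id
        )
        if not base.ok or base.objective_value is None:
            raise RuntimeError("cannot establish growth floor: base TFA failed")
        floor = gamma * base.objective_value
        rid = self.model.biomass_reaction_id
        for prefix in (REF, PERT):
            self.problem.add_constraint(
                {fwd(rid, prefix): 1.0, bwd(rid, prefix): -1.0}, floor, math.inf
            )

    def _finalize(self) -> None:
        self.problem.set_objective(
            {self._zvar(cid): 1.0 for cid in self.candidates}, sense="max"
        )

    # -- solving ------------------------------------------------------------

    def solve_mcs(self) -> ConsistencyResult:
        """Maximize the number of active candidate constraints."""
        if not self.candidates:
            return ConsistencyResult(
                status="optimal", tmcs=0, mcs=0, tmcs_gene_level=0
            )
        sol = self.problem.solve(
            time_limit=self.settings.solver_time_limit, mip_gap=self.settings.mip_gap
        )
        if not sol.ok and not sol.values:
            return ConsistencyResult(
                status=sol.status,
                tmcs=self.tmcs,
                mcs=0,
                tmcs_gene_level=self.tmcs_gene_level,
            )
        active = sorted(
            cid for cid in self.candidates if sol.values[self._zvar(cid)] > 0.5
        )
        return ConsistencyResult(
            status=sol.status,
            tmcs=self.tmcs,
            mcs=len(active),
            active_set=active,
            tmcs_gene_level=self.tmcs_gene_level,
        )

    def enumerate_alternatives(
        self, mcs: int, max_alternatives: Optional[int] = None
    ) -> list[list[str]]:
        """All (up to ``max_alternatives``) distinct active sets of size MCS.

        Integer cuts: after each solution Z, add sum_{i in Z} z_i <= MCS - 1
        with sum z = MCS pinned; stop at infeasibility or the cap.
        """
        if mcs <= 0 or not self.candidates:
            return []
        limit = max_alternatives or self.settings.max_alternatives
        zvars = {self._zvar(cid): 1.0 for cid in self.candidates}
        pin = self.problem.add_constraint(zvars, mcs, mcs)
        cuts = [pin]
        sets: list[list[str]] = []
        while len(sets) < limit:
            sol = self.problem.solve(
                time_limit=self.settings.solver_time_limit,
                mip_gap=self.settings.mip_gap,
            )
            if not sol.ok:
                break
            active = sorted(
                cid for cid in self.candidates if sol.values[self._zvar(cid)] > 0.5
            )
            sets.append(active)
            cuts.append(
                self.problem.add_constraint(
                    {self._zvar(cid): 1.0 for cid in active}, -math.inf, mcs - 1
                )
            )
        for row in cuts:
            self.problem.remove_constraint(row)
        return sets

    def _fix_active_set(self, active_set: Iterable[str]) -> list[tuple[str, float, float]]:
        """Pin every z to membership in the active set; returns saved bounds."""
        active = set(active_set)
        unknown = active - set(self.candidates)
        if unknown:
            raise KeyError(f"unknown candidate(s): {sorted(unknown)}")
        saved = []
        for cid in self.candidates:
            name = self._zvar(cid)
            saved.append((name, *self.problem.get_bounds(name)))
            val = 1.0 if cid in active else 0.0
            self.problem.set_bounds(name, val, val)
        return saved

    def _restore(self, saved: list[tuple[str, float, float]]) -> None:
        for name, lb, ub in saved:
            self.problem.set_bounds(name, lb, ub)

    def _maximize(self, objective: dict[str, float], active_set: Iterable[str]):
        saved = self._fix_active_set(active_set)
        self.problem.set_objective(objective, sense="max")
        try:
            sol = self.problem.solve(
                time_limit=self.settings.solver_time_limit,
                mip_gap=self.settings.mip_gap,
            )
        finally:
            self._restore(saved)
            self._finalize()
        return sol

    def condition_growth(
        self, active_set: Iterable[str]
    ) -> tuple[float, float]:
        """Max biomass flux in each condition with the indicators pinned."""
        rid = self.model.biomass_reaction_id
        if rid is None:
            raise RuntimeError("model has no biomass reaction")
        active = list(active_set)
        growths = []
        for prefix in (REF, PERT):
            sol = self._maximize(
                {fwd(rid, prefix): 1.0, bwd(rid, prefix): -1.0}, active
            )
            if not sol.ok:
                raise RuntimeError(
                    f"active set infeasible for growth maximization "
                    f"({'reference' if prefix == REF else 'perturbed'} copy); "
                    f"active candidates: {active}"
                )
            growths.append(sol.objective)
        return growths[0], growths[1]

    def max_production(
        self, met_id: str, condition: str, active_set: Iterable[str]
    ) -> float:
        """Max demand flux for a biomass precursor in one condition copy.

        ``condition`` is "reference" or "perturbed".  Returns 0.0 when the
        demand cannot be satisfied (blocked under the active constraints).
        """
        if met_id not in self._demand_metabolites:
            raise KeyError(
                f"{met_id!r} has no demand sink (not a biomass precursor?)"
            )
        prefix = REF if condition == "reference" else PERT
        name = f"{prefix}dem[{met_id}]"
        self.problem.set_bounds(name, 0.0, DEFAULT_BOUND)
        try:
            sol = self._maximize({name: 1.0}, active_set)
        finally:
            self.problem.set_bounds(name, 0.0, 0.0)
        if not sol.ok:
            return 0.0
        return max(sol.objective, 0.0)


def build_remi_problem(
    model: MetabolicModel,
    omics: OmicsData,
    settings: Optional[RemiSettings] = None,
    thermo: Optional[ThermoAnnotation] = None,
    tfa_settings: Optional[TFASettings] = None,
) -> RemiProblem:
    """Construct the two-condition MILP for a variant (tgex | tm | tgexm)."""
    settings = settings or RemiSettings()
    tfa_settings = tfa_settings or TFASettings()
    rp = RemiProblem(model, settings, thermo, tfa_settings)
    rp._add_condition_copies()
    if settings.variant in ("tgex", "tgexm"):
        for reg in map_expression_to_reactions(
            model, omics, settings.fold_threshold, settings.fdr_cutoff
        ):
            rp._add_reaction_candidate(reg)
    if settings.variant in ("tm", "tgexm"):
        for mid in sorted(omics.significant_metabolites()):
            rp._add_metabolite_candidate(mid, omics.metabolite_records[mid].ratio)
    rp._add_growth_floor()
    rp._finalize()
    return rp


# ---------------------------------------------------------------------------
# Post-processing of alternatives
# ---------------------------------------------------------------------------


def common_and_variable_constraints(
    alternatives: list[list[str]],
) -> tuple[dict[str, str], dict[str, str]]:
    """Intersection and (union minus intersection) over alternative active
    sets, each item labeled by source ('gene' | 'metabolite')."""
    if not alternatives:
        raise ValueError("need at least one alternative")
    sets = [set(a) for a in alternatives]
    common = set.intersection(*sets)
    union = set.union(*sets)
    varying = union - common
    return (
        {cid: candidate_source(cid) for cid in sorted(common)},
        {cid: candidate_source(cid) for cid in sorted(varying)},
    )


def select_representative(
    problem: RemiProblem,
    alternatives: list[list[str]],
    precursors: Optional[list[str]] = None,
) -> int:
    """Index of the most representative alternative.

    For every alternative, compute the vector of maximal biomass-precursor
    productions in both conditions; the representative minimizes the L1
    distance to the element-wise median vector (ties broken by first index).
    """
    import numpy as np

    if not alternatives:
        raise ValueError("need at least one alternative")
    if len(alternatives) == 1:
        return 0
    precursors = precursors or sorted(problem._demand_metabolites)
    vectors = []
    for active in alternatives:
        vec = []
        for mid in precursors:
            vec.append(problem.max_production(mid, "reference", active))
            vec.append(problem.max_production(mid, "perturbed", active))
        vectors.append(vec)
    arr = np.asarray(vectors)
    median = np.median(arr, axis=0)
    dists = np.abs(arr - median).sum(axis=1)
    return int(np.argmin(dists))


def solve_remi(
    model: MetabolicModel,
    omics: OmicsData,
    settings: Optional[RemiSettings] = None,
    thermo: Optional[ThermoAnnotation] = None,
    tfa_settings: Optional[TFASettings] = None,
    enumerate_alts: bool = True,
) -> tuple[RemiProblem, ConsistencyResult]:
    """End-to-end convenience: build, maximize consistency, enumerate
    alternatives and compute per-condition growth for the first optimum."""
    problem = build_remi_problem(model, omics, settings, thermo, tfa_settings)
    result = problem.solve_mcs()
    if result.mcs > 0:
        if enumerate_alts:
            result.alternatives = problem.enumerate_alternatives(result.mcs)
            if result.alternatives:
                result.active_set = result.alternatives[0]
        growth = problem.condition_growth(result.active_set)
        result.growth_reference, result.growth_perturbed = growth
    elif result.status == "optimal" and problem.model.biomass_reaction_id:
        growth = problem.condition_growth([])
        result.growth_reference, result.growth_perturbed = growth
    return problem, result
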