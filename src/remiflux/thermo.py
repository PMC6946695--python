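"""FBA, FVA and thermodynamics-based flux analysis (TFA).

FBA maximizes an objective flux subject to steady state (S.v = 0) and flux
bounds.  TFA augments this with Gibbs-energy coupling: for every reaction r
with known standard Gibbs energy, the transformed reaction energy

    dG_r = dG_r'0 + R*T * sum_m s_mr * ln(c_m)

is tied to the flux direction through binaries u+ and u-:

    u+ + u- <= 1
    f_r <= M * u+          b_r <= M * u-
    dG_r <= -delta + K * (1 - u+)
   -dG_r <= -delta + K * (1 - u-)

so forward (backward) flux requires a negative (positive) driving force of
at least ``delta``.  Fluxes are split v = f - b with f, b >= 0.  Metabolite
activities enter through bounded log-concentration variables; species with
fixed activity (protons, water) are excluded from the ln-concentration sum.
Reactions or metabolites without Gibbs data simply keep their flux bounds —
thermodynamics only ever removes solutions, so the TFA optimum never exceeds
the FBA optimum and equals it when the annotation is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .lp import LinearProblem, LPSolution
from .model import FluxSolution, MetabolicModel, Reaction

GAS_CONSTANT = 8.314e-3  # kJ mol^-1 K^-1
DEFAULT_TEMPERATURE = 303.15  # K; cultures grown at 30 degrees C

#: Species treated at fixed activity and excluded from ln-concentration terms,
#: matched on the compartment-stripped metabolite id (case-insensitive).
FIXED_ACTIVITY_SPECIES = frozenset({"h", "h2o", "proton", "water", "oh"})

#: Reaction kinds that carry thermodynamic constraints.  Boundary
#: pseudo-reactions (exchange/demand/biomass) have no defined reaction energy.
THERMO_KINDS = frozenset({"metabolic", "transport"})


@dataclass
class ThermoAnnotation:
    """Standard Gibbs energies and metabolite concentration bounds.

    ``dGr_std`` entries take precedence; otherwise a reaction's standard
    energy is derived as sum_m s_mr * dGf_std[m] when every participant has a
    formation energy.  Concentration bounds are mol/L, defaulting to
    1e-7..1e-1 (physiological range) and overridable per metabolite.
    """

    dGf_std: dict[str, float] = field(default_factory=dict)
    dGr_std: dict[str, float] = field(default_factory=dict)
    conc_lb: dict[str, float] = field(default_factory=dict)
    conc_ub: dict[str, float] = field(default_factory=dict)
    default_conc_lb: float = 1e-7
    default_conc_ub: float = 1e-1
    temperature: float = DEFAULT_TEMPERATURE
    gas_constant: float = GAS_CONSTANT
    excluded_species: frozenset = FIXED_ACTIVITY_SPECIES

    def __post_init__(self):
        for mid in set(self.conc_lb) | set(self.conc_ub):
            lb = self.conc_lb.get(mid, self.default_conc_lb)
            ub = self.conc_ub.get(mid, self.default_conc_ub)
            if not (0 < lb <= ub):
                raise ValueError(f"bad concentration bounds for {mid!r}: [{lb}, {ub}]")

    @property
    def rt(self) -> float:
        return self.gas_constant * self.temperature

    def is_empty(self) -> bool:
        return not self.dGf_std and not self.dGr_std

    def concentration_bounds(self, met_id: str) -> tuple[float, float]:
        return (
            self.conc_lb.get(met_id, self.default_conc_lb),
            self.conc_ub.get(met_id, self.default_conc_ub),
        )

    def is_fixed_activity(self, model: MetabolicModel, met_id: str) -> bool:
        met = model.metabolites[met_id]
        base = met_id
        if base.endswith("_" + met.compartment):
            base = base[: -len(met.compartment) - 1]
        return base.lower() in self.excluded_species

    def reaction_dgr0(self, model: MetabolicModel, rxn: Reaction) -> Optional[float]:
        """Standard reaction energy, direct or derived from formation energies."""
        if rxn.id in self.dGr_std:
            return self.dGr_std[rxn.id]
        total = 0.0
        for mid, coef in rxn.stoichiometry.items():
            if mid not in self.dGf_std:
                return None
            total += coef * self.dGf_std[mid]
        return total

    def covered_reactions(self, model: MetabolicModel) -> set[str]:
        return {
            rid
            for rid, rxn in model.reactions.items()
            if rxn.kind in THERMO_KINDS and self.reaction_dgr0(model, rxn) is not None
        }

    def coverage(self, model: MetabolicModel) -> dict[str, float]:
        """Fraction of metabolites with dGf and of eligible reactions with dGr'0."""
        n_met = len(model.metabolites)
        eligible = [r for r in model.reactions.values() if r.kind in THERMO_KINDS]
        covered = self.covered_reactions(model)
        return {
            "metabolite_coverage": (
                sum(1 for m in model.metabolites if m in self.dGf_std) / n_met
                if n_met
                else 0.0
            ),
            "reaction_coverage": (
                len(covered) / len(eligible) if eligible else 0.0
            ),
        }


@dataclass
class TFASettings:
    """Numerical knobs for the direction-coupling MILP.

    big_M bounds the split fluxes (must exceed every |flux bound|); K bounds
    |dG_r| when a direction is off; delta is the minimal driving force in
    kJ/mol.
    """

    big_M: float = 1000.0
    dG_margin: float = 0.0  # delta
    K: float = 1e5
    solver_time_limit: Optional[float] = None
    feasibility_tol: float = 1e-9
    mip_gap: float = 1e-6

    def __post_init__(self):
        if self.dG_margin < 0:
            raise ValueError("dG_margin must be >= 0")


# ---------------------------------------------------------------------------
# Problem construction (shared with REMI, which builds two prefixed copies)
# ---------------------------------------------------------------------------


def fwd(rid: str, prefix: str = "") -> str:
    return f"{prefix}f[{rid}]"


def bwd(rid: str, prefix: str = "") -> str:
    return f"{prefix}b[{rid}]"


def dg_var(rid: str, prefix: str = "") -> str:
    return f"{prefix}dG[{rid}]"


def lnc_var(mid: str, prefix: str = "") -> str:
    return f"{prefix}lnc[{mid}]"


def add_flux_variables(
    problem: LinearProblem, model: MetabolicModel, prefix: str = ""
) -> None:
    """Split fluxes f, b >= 0 per reaction plus steady-state rows per metabolite.

    A positive lower bound becomes a lower bound on f (and pins b to 0);
    a negative upper bound mirrors onto b."""
    for rid, rxn in model.reactions.items():
        problem.add_variable(
            fwd(rid, prefix), max(rxn.lower_bound, 0.0), max(rxn.upper_bound, 0.0)
        )
        problem.add_variable(
            bwd(rid, prefix), max(-rxn.upper_bound, 0.0), max(-rxn.lower_bound, 0.0)
        )
    for mid in model.metabolites:
        coeffs: dict[str, float] = {}
        for rid, rxn in model.reactions.items():
            coef = rxn.stoichiometry.get(mid)
            if coef:
                coeffs[fwd(rid, prefix)] = coef
                coeffs[bwd(rid, prefix)] = -coef
        if coeffs:
            problem.add_constraint(coeffs, 0.0, 0.0)


def add_thermo_constraints(
    problem: LinearProblem,
    model: MetabolicModel,
    thermo: ThermoAnnotation,
    settings: TFASettings,
    prefix: str = "",
) -> set[str]:
    """Attach Gibbs-direction coupling for covered reactions; returns their ids."""
    covered = thermo.covered_reactions(model)
    if not covered:
        return covered
    rt = thermo.rt
    lnc_added: set[str] = set()
    for rid in sorted(covered):
        rxn = model.reactions[rid]
        dgr0 = thermo.reaction_dgr0(model, rxn)
        # dG_r - RT * sum s_mr ln c_m = dGr'0 over variable-activity species
        row: dict[str, float] = {}
        problem.add_variable(dg_var(rid, prefix), -math.inf, math.inf)
        row[dg_var(rid, prefix)] = 1.0
        for mid, coef in rxn.stoichiometry.items():
            if thermo.is_fixed_activity(model, mid):
                continue
            name = lnc_var(mid, prefix)
            if mid not in lnc_added and not problem.has_variable(name):
                clb, cub = thermo.concentration_bounds(mid)
                problem.add_variable(name, math.log(clb), math.log(cub))
                lnc_added.add(mid)
            row[name] = row.get(name, 0.0) - rt * coef
        problem.add_constraint(row, dgr0, dgr0)

        uf = problem.add_variable(f"{prefix}uf[{rid}]", binary=True)
        ub = problem.add_variable(f"{prefix}ub[{rid}]", binary=True)
        problem.add_constraint({uf: 1.0, ub: 1.0}, -math.inf, 1.0)
        problem.add_constraint(
            {fwd(rid, prefix): 1.0, uf: -settings.big_M}, -math.inf, 0.0
        )
        problem.add_constraint(
            {bwd(rid, prefix): 1.0, ub: -settings.big_M}, -math.inf, 0.0
        )
        # dG <= -delta + K(1-u+)  <=>  dG + K*u+ <= K - delta
        problem.add_constraint(
            {dg_var(rid, prefix): 1.0, uf: settings.K},
            -math.inf,
            settings.K - settings.dG_margin,
        )
        problem.add_constraint(
            {dg_var(rid, prefix): -1.0, ub: settings.K},
            -math.inf,
            settings.K - settings.dG_margin,
        )
    return covered


def _extract_solution(
    model: MetabolicModel, sol: LPSolution, prefix: str = ""
) -> FluxSolution:
    if not sol.ok and not sol.values:
        return FluxSolution(status=sol.status)
    fluxes = {
        rid: sol.values[fwd(rid, prefix)] - sol.values[bwd(rid, prefix)]
        for rid in model.reactions
    }
    extras = {
        name: value
        for name, value in sol.values.items()
        if name.startswith(f"{prefix}dG[") or name.startswith(f"{prefix}lnc[")
    }
    return FluxSolution(
        status=sol.status, objective_value=sol.objective, fluxes=fluxes, extras=extras
    )


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------


def build_fba_problem(model: MetabolicModel) -> LinearProblem:
    problem = LinearProblem(f"fba:{model.id}")
    add_flux_variables(problem, model)
    return problem


def solve_fba(model: MetabolicModel, objective_reaction: Optional[str] = None) -> FluxSolution:
    """Maximize the objective flux (biomass by default) under S.v=0 and bounds."""
    objective_reaction = objective_reaction or model.biomass_reaction_id
    if objective_reaction not in model.reactions:
        raise KeyError(f"objective reaction {objective_reaction!r} not in model")
    problem = build_fba_problem(model)
    problem.set_objective({fwd(objective_reaction): 1.0, bwd(objective_reaction): -1.0})
    return _extract_solution(model, problem.solve())


def solve_tfa(
    model: MetabolicModel,
    thermo: Optional[ThermoAnnotation] = None,
    settings: Optional[TFASettings] = None,
    objective_reaction: Optional[str] = None,
) -> FluxSolution:
    """TFA optimum: FBA plus Gibbs-direction coupling for covered reactions.

    With an empty (or absent) annotation this reduces exactly to FBA.  The
    returned solution carries dG_r and ln c_m values in ``extras``.
    """
    thermo = thermo or ThermoAnnotation()
    settings = settings or TFASettings()
    objective_reaction = objective_reaction or model.biomass_reaction_id
    if objective_reaction not in model.reactions:
        raise KeyError(f"objective reaction {objective_reaction!r} not in model")
    problem = LinearProblem(f"tfa:{model.id}")
    add_flux_variables(problem, model)
    add_thermo_constraints(problem, model, thermo, settings)
    problem.set_objective({fwd(objective_reaction): 1.0, bwd(objective_reaction): -1.0})
    sol = problem.solve(time_limit=settings.solver_time_limit, mip_gap=settings.mip_gap)
    return _extract_solution(model, sol)


def flux_variability(
    model: MetabolicModel,
    reactions: Optional[Iterable[str]] = None,
    objective_fraction: float = 0.0,
    objective_reaction: Optional[str] = None,
    use_thermo: bool = False,
    thermo: Optional[ThermoAnnotation] = None,
    settings: Optional[TFASettings] = None,
) -> dict[str, tuple[float, float]]:
    """Per-reaction (min, max) flux with objective >= fraction * optimum.

    ``objective_fraction=0`` probes absolute flux capability (the blocked-
    reaction detection instrument); no objective constraint is added then.
    """
    settings = settings or TFASettings()
    reactions = list(reactions) if reactions is not None else list(model.reactions)
    for rid in reactions:
        if rid not in model.reactions:
            raise KeyError(f"unknown reaction {rid!r}")
    problem = LinearProblem(f"fva:{model.id}")
    add_flux_variables(problem, model)
    if use_thermo and thermo is not None:
        add_thermo_constraints(problem, model, thermo, settings)

    if objective_fraction > 0:
        obj_rid = objective_reaction or model.biomass_reaction_id
        if obj_rid not in model.reactions:
            raise KeyError(f"objective reaction {obj_rid!r} not in model")
        problem.set_objective({fwd(obj_rid): 1.0, bwd(obj_rid): -1.0})
        base = problem.solve(time_limit=settings.solver_time_limit)
        if not base.ok:
            raise RuntimeError(f"base model not solvable: status={base.status}")
        problem.add_constraint(
            {fwd(obj_rid): 1.0, bwd(obj_rid): -1.0},
            objective_fraction * base.objective,
            math.inf,
        )

    ranges: dict[str, tuple[float, float]] = {}
    for rid in reactions:
        obj = {fwd(rid): 1.0, bwd(rid): -1.0}
        problem.set_objective(obj, sense="min")
        lo = problem.solve(time_limit=settings.solver_time_limit)
        problem.set_objective(obj, sense="max")
        hi = problem.solve(time_limit=settings.solver_time_limit)
        if not lo.ok or not hi.ok:
            raise RuntimeError(f"FVA subproblem failed for {rid!r}")
        ranges[rid] = (lo.objective, hi.objective)
    return ranges


def estimate_uptake_for_growth(
    model: MetabolicModel,
    thermo: Optional[ThermoAnnotation],
    uptake_reaction: str,
    target_growth: float,
    settings: Optional[TFASettings] = None,
) -> Optional[float]:
    """Minimal uptake magnitude (mmol gDW^-1 h^-1) supporting a target growth.

    Fixes biomass >= target and minimizes the total (forward+backward) flux
    through the named exchange; returns the magnitude, or None when the
    target is unreachable within bounds.
    """
    settings = settings or TFASettings()
    rxn = model.reactions.get(uptake_reaction)
    if rxn is None or rxn.kind != "exchange":
        raise KeyError(f"{uptake_reaction!r} is not an exchange reaction")
    biomass = model.biomass_reaction_id
    problem = LinearProblem(f"uptake:{model.id}")
    add_flux_variables(problem, model)
    if thermo is not None and not thermo.is_empty():
        add_thermo_constraints(problem, model, thermo, settings)
    problem.add_constraint(
        {fwd(biomass): 1.0, bwd(biomass): -1.0}, target_growth, math.inf
    )
    problem.set_objective(
        {fwd(uptake_reaction): 1.0, bwd(uptake_reaction): 1.0}, sense="min"
    )
    sol = problem.solve(time_limit=settings.solver_time_limit)
    if not sol.ok:
        return None
    return sol.objective


# ---------------------------------------------------------------------------
# Thermo annotation I/O (TSV)
# ---------------------------------------------------------------------------


def load_thermo_tsv(path) -> ThermoAnnotation:
    """Read a thermo table: columns id, type(metabolite|reaction), dG, conc_lb, conc_ub."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    thermo = ThermoAnnotation()
    for _, row in df.iterrows():
        kind = str(row.get("type", "metabolite")).strip().lower()
        ident = str(row["id"])
        if kind == "reaction":
            if not pd.isna(row.get("dG")):
                thermo.dGr_std[ident] = float(row["dG"])
        else:
            if not pd.isna(row.get("dG")):
                thermo.dGf_std[ident] = float(row["dG"])
            if "conc_lb" in df.columns and not pd.isna(row.get("conc_lb")):
                thermo.conc_lb[ident] = float(row["conc_lb"])
            if "conc_ub" in df.columns and not pd.isna(row.get("conc_ub")):
                thermo.conc_ub[ident] = float(row["conc_ub"])
    return thermo


def write_thermo_tsv(thermo: ThermoAnnotation, path) -> None:
    import pandas as pd

    rows = []
    for mid in sorted(set(thermo.dGf_std) | set(thermo.conc_lb) | set(thermo.conc_ub)):
        rows.append(
            {
                "id": mid,
                "type": "metabolite",
                "dG": thermo.dGf_std.get(mid, float("nan")),
                "conc_lb": thermo.conc_lb.get(mid, float("nan")),
                "conc_ub": thermo.conc_ub.get(mid, float("nan")),
            }
        )
    for rid in sorted(thermo.dGr_std):
        rows.append(
            {
                "id": rid,
                "type": "reaction",
                "dG": thermo.dGr_std[rid],
                "conc_lb": float("nan"),
                "conc_ub": float("nan"),
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), sep="\t", index=False)
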