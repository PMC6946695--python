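"""Independent brute-force / direct-LP oracles used to cross-check the
package's MILP-based implementations.

Everything here assembles problems directly with ``scipy.optimize.linprog``
on net flux variables (no split fluxes, no shared builder code with
``remiflux.lp``), or enumerates exhaustively, so agreement with the package
is a genuine dual-route check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import linprog

from remiflux.model import MetabolicModel


def _net_flux_arrays(model: MetabolicModel):
    """S (dense), bounds arrays and the reaction-id order, on net fluxes v."""
    S, met_ids, rxn_ids = model.stoichiometric_matrix()
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
    return S, lb, ub, rxn_ids


def fba_oracle(model: MetabolicModel, objective_reaction: str) -> float:
    """LP optimum of max v_obj s.t. S v = 0, lb <= v <= ub (net fluxes)."""
    S, lb, ub, rxn_ids = _net_flux_arrays(model)
    c = np.zeros(len(rxn_ids))
    c[rxn_ids.index(objective_reaction)] = -1.0
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)), method="highs"
    )
    assert res.status == 0, f"oracle LP failed: {res.message}"
    return -res.fun


def fva_oracle(model: MetabolicModel, reaction_id: str) -> tuple[float, float]:
    """Per-reaction min/max flux, no objective constraint."""
    S, lb, ub, rxn_ids = _net_flux_arrays(model)
    j = rxn_ids.index(reaction_id)
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(len(rxn_ids))
        c[j] = sign
        res = linprog(
            c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)),
            method="highs",
        )
        assert res.status == 0, f"oracle LP failed: {res.message}"
        out.append(sign * res.fun)
    return out[0], out[1]


def blocked_oracle(model: MetabolicModel, tol: float = 1e-6) -> set[str]:
    """Blocked = |min v| and |max v| both below tol, exchanges opened."""
    probe = model.copy()
    for rxn in probe.reactions.values():
        if rxn.kind == "exchange":
            rxn.lower_bound, rxn.upper_bound = -1000.0, 1000.0
    blocked = set()
    for rid in probe.reactions:
        lo, hi = fva_oracle(probe, rid)
        if abs(lo) <= tol and abs(hi) <= tol:
            blocked.add(rid)
    return blocked


# ---------------------------------------------------------------------------
# TFA: exhaustive direction-pattern enumeration
# ---------------------------------------------------------------------------


def tfa_direction_enumeration(
    model: MetabolicModel,
    thermo,
    objective_reaction: str,
    delta: float = 0.0,
) -> float:
    """Max objective over all thermodynamically admissible direction patterns.

    Every covered reaction is assigned forward / backward / off; a pattern is
    admissible when log-concentrations exist making each assigned direction's
    Gibbs energy favorable (<= -delta forward, >= delta backward); the flux
    LP is then solved with signs restricted.  Feasible only for a handful of
    covered reactions (3^k patterns).
    """
    covered = sorted(thermo.covered_reactions(model))
    assert len(covered) <= 8, "oracle only meant for small covered sets"
    rt = thermo.rt
    var_mets = sorted(
        {
            mid
            for rid in covered
            for mid in model.reactions[rid].stoichiometry
            if not thermo.is_fixed_activity(model, mid)
        }
    )
    met_index = {m: i for i, m in enumerate(var_mets)}
    best = -math.inf
    for pattern in itertools.product((1, -1, 0), repeat=len(covered)):
        # concentration feasibility LP for the assigned directions
        A_ub, b_ub = [], []
        ok = True
        for rid, direction in zip(covered, pattern):
            if direction == 0:
                continue
            dgr0 = thermo.reaction_dgr0(model, model.reactions[rid])
            row = np.zeros(len(var_mets))
            for mid, coef in model.reactions[rid].stoichiometry.items():
                if mid in met_index:
                    row[met_index[mid]] += rt * coef
            # forward: dgr0 + row.x <= -delta ; backward: >= delta
            A_ub.append(direction * row)
            b_ub.append(-delta - direction * dgr0)
        if A_ub:
            bounds = [
                (math.log(thermo.concentration_bounds(m)[0]),
                 math.log(thermo.concentration_bounds(m)[1]))
                for m in var_mets
            ]
            res = linprog(
                np.zeros(len(var_mets)),
                A_ub=np.array(A_ub),
                b_ub=np.array(b_ub),
                bounds=bounds,
                method="highs",
            )
            ok = res.status == 0
        if not ok:
            continue
        restricted = model.copy()
        for rid, direction in zip(covered, pattern):
            rxn = restricted.reactions[rid]
            if direction == 1:
                rxn.lower_bound = max(rxn.lower_bound, 0.0)
            elif direction == -1:
                rxn.upper_bound = min(rxn.upper_bound, 0.0)
            else:
                rxn.lower_bound = rxn.upper_bound = 0.0
        S, lb, ub, rxn_ids = _net_flux_arrays(restricted)
        c = np.zeros(len(rxn_ids))
        c[rxn_ids.index(objective_reaction)] = -1.0
        res = linprog(
            c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lb, ub)),
            method="highs",
        )
        if res.status == 0:
            best = max(best, -res.fun)
    return best


# ---------------------------------------------------------------------------
# Consistency maximization: exhaustive subset search
# ---------------------------------------------------------------------------


def _candidate_rows(model, candidates, settings, n, index_f, index_b):
    """Per-candidate inequality rows over [f_ref, b_ref, f_pert, b_pert]."""

    def act(rid, cond):
        row = np.zeros(4 * n)
        row[index_f(rid, cond)] = 1.0
        row[index_b(rid, cond)] = 1.0
        return row

    def prod(mid, cond):
        row = np.zeros(4 * n)
        for rid, rxn in model.reactions.items():
            if rxn.kind == "exchange":
                continue
            coef = rxn.stoichiometry.get(mid)
            if not coef:
                continue
            if coef > 0:
                row[index_f(rid, cond)] += coef
            else:
                row[index_b(rid, cond)] += -coef
        return row

    eps = settings.min_activity
    rows = {}
    for cand in candidates:
        rho = min(max(cand.ratio, 1.0 / settings.ratio_cap), settings.ratio_cap)
        vec = act if cand.kind == "reaction" else prod
        if cand.direction == "up":
            factor, donor, receiver = rho, "ref", "pert"
        else:
            factor, donor, receiver = 1.0 / rho, "pert", "ref"
        # receiver >= factor * donor  and  donor >= eps  (as A_ub x <= b_ub)
        rows[cand.candidate_id] = [
            (factor * vec(cand.target, donor) - vec(cand.target, receiver), 0.0),
            (-vec(cand.target, donor), -eps),
        ]
    return rows


def remi_subset_feasible(model, candidates, subset, settings) -> bool:
    """Direct LP: are the given candidate constraints jointly satisfiable?"""
    rxn_ids = list(model.reactions)
    n = len(rxn_ids)
    pos = {r: i for i, r in enumerate(rxn_ids)}

    def index_f(rid, cond):
        return pos[rid] + (0 if cond == "ref" else 2 * n)

    def index_b(rid, cond):
        return pos[rid] + n + (0 if cond == "ref" else 2 * n)

    S, met_ids, _ = model.stoichiometric_matrix()
    A_eq = np.zeros((2 * S.shape[0], 4 * n))
    A_eq[: S.shape[0], :n] = S
    A_eq[: S.shape[0], n : 2 * n] = -S
    A_eq[S.shape[0] :, 2 * n : 3 * n] = S
    A_eq[S.shape[0] :, 3 * n :] = -S
    bounds = []
    for _ in ("ref", "pert"):
        for rid in rxn_ids:
            bounds.append((0.0, max(model.reactions[rid].upper_bound, 0.0)))
        for rid in rxn_ids:
            bounds.append((0.0, max(-model.reactions[rid].lower_bound, 0.0)))
    rows = _candidate_rows(
        model, candidates, settings, n, index_f, index_b
    )
    A_ub, b_ub = [], []
    chosen = {c.candidate_id for c in candidates} & set(subset)
    for cid in chosen:
        for row, rhs in rows[cid]:
            A_ub.append(row)
            b_ub.append(rhs)
    res = linprog(
        np.zeros(4 * n),
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        A_ub=np.array(A_ub) if A_ub else None,
        b_ub=np.array(b_ub) if b_ub else None,
        bounds=bounds,
        method="highs",
    )
    return res.status == 0


def mcs_brute_force(model, candidates, settings) -> tuple[int, list[list[str]]]:
    """Exhaustive-subset MCS plus all optimal active sets.

    Scans subset sizes descending; the first size with a feasible subset is
    the MCS, and every feasible subset of that size is an optimal active set.
    """
    ids = [c.candidate_id for c in candidates]
    for size in range(len(ids), -1, -1):
        feasible = [
            sorted(subset)
            for subset in itertools.combinations(ids, size)
            if remi_subset_feasible(model, candidates, set(subset), settings)
        ]
        if feasible:
            return size, feasible
    return 0, [[]]


# ---------------------------------------------------------------------------
# Gap-filling: exhaustive subset search
# ---------------------------------------------------------------------------


def gapfill_subset_feasible(model, universal_db, subset, target, min_flux) -> bool:
    """Can the target reaction carry >= min_flux forward with only these
    database reactions merged in (exchanges opened)?"""
    merged = model.copy()
    for rxn in merged.reactions.values():
        if rxn.kind == "exchange":
            rxn.lower_bound, rxn.upper_bound = -1000.0, 1000.0
    for rid in subset:
        rxn = universal_db.reactions[rid]
        for mid in rxn.stoichiometry:
            if mid not in merged.metabolites:
                merged.metabolites[mid] = universal_db.metabolites[mid]
                merged.compartments.setdefault(
                    universal_db.metabolites[mid].compartment, "x"
                )
        import copy

        merged.reactions[rid] = copy.deepcopy(rxn)
    if target not in merged.reactions:
        return False
    S, lb, ub, rxn_ids = _net_flux_arrays(merged)
    lb = lb.copy()
    lb[rxn_ids.index(target)] = max(lb[rxn_ids.index(target)], min_flux)
    res = linprog(
        np.zeros(len(rxn_ids)),
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res.status == 0


def gapfill_brute_force(model, universal_db, target, min_flux=1e-3):
    """Smallest db subset activating the target (None when unfillable)."""
    candidates = [r for r in universal_db.reactions if r not in model.reactions]
    assert len(candidates) <= 8, "oracle only meant for small databases"
    for size in range(0, len(candidates) + 1):
        sets = [
            sorted(subset)
            for subset in itertools.combinations(candidates, size)
            if gapfill_subset_feasible(model, universal_db, subset, target, min_flux)
        ]
        if sets:
            return size, sets
    return None, []
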