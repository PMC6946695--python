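"""Thin named-variable LP/MILP layer over scipy's HiGHS interface.

Every optimization in this package (FBA, TFA, FVA, gap-filling, consistency
maximization) is expressed as a :class:`LinearProblem`: named continuous or
binary variables, linear range constraints, and a linear objective.  Solving
goes through ``scipy.optimize.milp`` (HiGHS), which is deterministic on a
single thread — reruns of an identical problem give identical optima and,
for the problems built here, identical incumbents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

_STATUS = {
    0: "optimal",
    1: "time_limit",  # iteration/time limit reached
    2: "infeasible",
    3: "unbounded",
}


@dataclass
class LPSolution:
    status: str
    objective: Optional[float]
    values: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


class LinearProblem:
    """A mutable LP/MILP with named variables and range constraints."""

    def __init__(self, name: str = ""):
        self.name = name
        self._vars: list[str] = []
        self._index: dict[str, int] = {}
        self._lb: list[float] = []
        self._ub: list[float] = []
        self._integer: list[bool] = []
        # constraints as (coeff dict, lb, ub)
        self._rows: list[tuple[dict[str, float], float, float]] = []
        self._objective: dict[str, float] = {}
        self._sense = "max"

    # -- construction -------------------------------------------------------

    def add_variable(
        self,
        name: str,
        lb: float = 0.0,
        ub: float = np.inf,
        *,
        binary: bool = False,
    ) -> str:
        if name in self._index:
            raise ValueError(f"duplicate variable {name!r}")
        self._index[name] = len(self._vars)
        self._vars.append(name)
        if binary:
            lb, ub = max(lb, 0.0), min(ub, 1.0)
        self._lb.append(lb)
        self._ub.append(ub)
        self._integer.append(binary)
        return name

    def has_variable(self, name: str) -> bool:
        return name in self._index

    def set_bounds(self, name: str, lb: float, ub: float) -> None:
        i = self._index[name]
        self._lb[i] = lb
        self._ub[i] = ub

    def get_bounds(self, name: str) -> tuple[float, float]:
        i = self._index[name]
        return self._lb[i], self._ub[i]

    def add_constraint(
        self,
        coeffs: Mapping[str, float],
        lb: float = -np.inf,
        ub: float = np.inf,
    ) -> int:
        """Add lb <= sum coeffs[v]*v <= ub; returns the row index."""
        unknown = [v for v in coeffs if v not in self._index]
        if unknown:
            raise ValueError(f"unknown variable(s) {unknown} in constraint")
        self._rows.append((dict(coeffs), lb, ub))
        return len(self._rows) - 1

    def remove_constraint(self, row: int) -> None:
        """Neutralize a previously added constraint (keeps row indices stable)."""
        self._rows[row] = ({}, -np.inf, np.inf)

    def set_objective(self, coeffs: Mapping[str, float], sense: str = "max") -> None:
        if sense not in ("max", "min"):
            raise ValueError("sense must be 'max' or 'min'")
        self._objective = dict(coeffs)
        self._sense = sense

    @property
    def variables(self) -> Sequence[str]:
        return tuple(self._vars)

    # -- solving ------------------------------------------------------------

    def _matrices(self):
        n = len(self._vars)
        data, rows, cols = [], [], []
        clb, cub = [], []
        for i, (coeffs, lb, ub) in enumerate(self._rows):
            for var, coef in coeffs.items():
                rows.append(i)
                cols.append(self._index[var])
                data.append(coef)
            clb.append(lb)
            cub.append(ub)
        A = sparse.csr_matrix((data, (rows, cols)), shape=(len(self._rows), n))
        c = np.zeros(n)
        for var, coef in self._objective.items():
            c[self._index[var]] = coef
        if self._sense == "max":
            c = -c
        return A, np.array(clb), np.array(cub), c

    def solve(self, time_limit: Optional[float] = None, mip_gap: float = 1e-6) -> LPSolution:
        """Solve with HiGHS; relaxes to plain LP when no integer variables exist."""
        A, clb, cub, c = self._matrices()
        integrality = np.array(self._integer, dtype=int)
        options: dict = {"mip_rel_gap": mip_gap}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        res = milp(
            c=c,
            constraints=[LinearConstraint(A, clb, cub)] if A.shape[0] else [],
            bounds=Bounds(np.array(self._lb), np.array(self._ub)),
            integrality=integrality,
            options=options,
        )
        status = _STATUS.get(res.status, "failed")
        if res.x is None:
            # milp reports status 1 (limit) even with no incumbent
            if status == "time_limit":
                status = "infeasible"
            return LPSolution(status=status, objective=None)
        values = {name: float(res.x[i]) for i, name in enumerate(self._vars)}
        obj = float(res.fun) if res.fun is not None else None
        if obj is not None and self._sense == "max":
            obj = -obj
        return LPSolution(status=status, objective=obj, values=values)

    def solve_lp_relaxation(self) -> LPSolution:
        """Solve ignoring integrality (used for bound probing)."""
        A, clb, cub, c = self._matrices()
        # linprog wants A_ub x <= b_ub and A_eq x = b_eq; split range rows
        res = milp(
            c=c,
            constraints=[LinearConstraint(A, clb, cub)] if A.shape[0] else [],
            bounds=Bounds(np.array(self._lb), np.array(self._ub)),
            integrality=np.zeros(len(self._vars), dtype=int),
        )
        status = _STATUS.get(res.status, "failed")
        if res.x is None:
            return LPSolution(status=status, objective=None)
        values = {name: float(res.x[i]) for i, name in enumerate(self._vars)}
        obj = float(res.fun)
        if self._sense == "max":
            obj = -obj
        return LPSolution(status=status, objective=obj, values=values)
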