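"""Core data model for genome-scale metabolic networks.

A :class:`MetabolicModel` is a stoichiometric reconstruction: metabolites
assigned to compartments, reactions with flux bounds and gene–protein–reaction
(GPR) rules, and a designated biomass reaction whose flux is the specific
growth rate mu (h^-1).  The stoichiometric matrix S (metabolites x reactions)
is reconstructible from the per-reaction coefficient maps; steady state means
S.v = 0.

Reactions are classified by ``kind``:

* ``metabolic`` — intracellular chemistry,
* ``transport`` — moves species between compartments,
* ``exchange`` — system boundary, touches exactly one metabolite,
* ``demand`` — irreversible intracellular sink,
* ``biomass`` — the growth pseudo-reaction draining precursors.

Exchange, demand and biomass reactions are pseudo-reactions and are exempt
from elemental balancing.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Union

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0  # mmol gDW^-1 h^-1, community convention

REACTION_KINDS = ("metabolic", "transport", "exchange", "biomass", "demand")

#: Pseudo-elements that make a formula unverifiable rather than imbalanced
#: (generic residues in lumped biochemistry).
PSEUDO_ELEMENTS = frozenset({"R", "X"})


class ModelValidationError(ValueError):
    """Raised when a model (or file) violates a structural invariant."""


class ModelParseError(ValueError):
    """Raised when an input file cannot be parsed as a metabolic model."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

#: A GPR tree: a gene id, or ("and"|"or", [children]).  The empty rule is None.
GPRNode = Union[str, tuple]

_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(rule: str) -> Optional[GPRNode]:
    """Parse a boolean gene-association rule into an AND/OR tree.

    Grammar: identifiers, parentheses, case-insensitive ``and``/``or``; AND
    binds tighter than OR.  An empty or whitespace rule returns ``None``.

    Raises
    ------
    ModelParseError
        On unbalanced parentheses or dangling operators.
    """
    tokens = _GPR_TOKEN.findall(rule or "")
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRNode:
        children = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            children.append(parse_and())
        return children[0] if len(children) == 1 else ("or", children)

    def parse_and() -> GPRNode:
        children = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            children.append(parse_atom())
        return children[0] if len(children) == 1 else ("and", children)

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise ModelParseError(f"dangling operator in GPR rule {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise ModelParseError(f"unbalanced parentheses in GPR rule {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ModelParseError(f"unexpected token {tok!r} in GPR rule {rule!r}")
        return take()

    node = parse_or()
    if pos != len(tokens):
        raise ModelParseError(f"trailing tokens in GPR rule {rule!r}")
    return node


def gpr_genes(node: Optional[GPRNode]) -> set[str]:
    """Set of gene ids appearing in a GPR tree."""
    if node is None:
        return set()
    if isinstance(node, str):
        return {node}
    _, children = node
    out: set[str] = set()
    for child in children:
        out |= gpr_genes(child)
    return out


def evaluate_gpr(
    node: Optional[GPRNode],
    values: Mapping[str, float],
    and_rule: Callable[[Iterable[float]], float] = min,
    or_rule: Callable[[Iterable[float]], float] = max,
    missing: Optional[float] = None,
) -> Optional[float]:
    """Evaluate a GPR tree over per-gene values (AND=min, OR=max by default).

    Genes absent from ``values`` contribute ``missing``; when ``missing`` is
    None such genes are dropped, and a node with no evaluable children yields
    None (propagated upward).
    """
    if node is None:
        return None
    if isinstance(node, str):
        if node in values:
            return float(values[node])
        return missing
    op, children = node
    vals = [
        v
        for v in (evaluate_gpr(c, values, and_rule, or_rule, missing) for c in children)
        if v is not None
    ]
    if not vals:
        return None
    return and_rule(vals) if op == "and" else or_rule(vals)


def gpr_to_string(node: Optional[GPRNode]) -> str:
    """Serialize a GPR tree back to a rule string (canonical parenthesization)."""
    if node is None:
        return ""
    if isinstance(node, str):
        return node
    op, children = node
    sep = f" {op} "
    parts = []
    for child in children:
        text = gpr_to_string(child)
        if isinstance(child, tuple) and child[0] != op:
            text = f"({text})"
        parts.append(text)
    return sep.join(parts)


# ---------------------------------------------------------------------------
# Chemical formulas (Hill notation)
# ---------------------------------------------------------------------------

_ELEMENT = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation elemental formula into element counts.

    Raises :class:`ModelParseError` if the string is not a sequence of
    element symbols with optional integer counts (e.g. ``C6H12O6``).
    """
    pos = 0
    counts: dict[str, int] = {}
    for match in _ELEMENT.finditer(formula):
        if match.start() != pos:
            raise ModelParseError(f"invalid formula {formula!r}")
        element, num = match.groups()
        counts[element] = counts.get(element, 0) + (int(num) if num else 1)
        pos = match.end()
    if pos != len(formula):
        raise ModelParseError(f"invalid formula {formula!r}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Render element counts as a Hill-notation string (C, H, then alphabetic)."""
    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(
        f"{el}{counts[el]}" if counts[el] != 1 else el for el in order if counts[el]
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    compartment: str
    name: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None
    kegg_id: Optional[str] = None

    def element_counts(self) -> Optional[dict[str, int]]:
        if self.formula is None:
            return None
        return parse_formula(self.formula)


@dataclass
class Reaction:
    """One column of S: signed stoichiometric coefficients plus flux bounds."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: Optional[GPRNode] = None
    ec_numbers: list[str] = field(default_factory=list)
    subsystems: list[str] = field(default_factory=list)
    kind: str = "metabolic"
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def genes(self) -> set[str]:
        return gpr_genes(self.gpr)

    def gpr_string(self) -> str:
        return gpr_to_string(self.gpr)


@dataclass
class FluxSolution:
    """Outcome of an LP/MILP flux computation.

    ``objective_value`` is mu (h^-1) when the objective is biomass, otherwise
    a flux in mmol gDW^-1 h^-1.  ``extras`` carries auxiliary variable values
    (Gibbs energies, log-concentrations) when produced by TFA.
    """

    status: str  # optimal | infeasible | unbounded | time_limit
    objective_value: Optional[float] = None
    fluxes: dict[str, float] = field(default_factory=dict)
    extras: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


@dataclass
class BalanceIssue:
    """A per-reaction elemental bookkeeping problem.

    ``kind`` is ``"imbalanced"`` (element and signed excess given) or
    ``"unverifiable"`` (a participant lacks a formula or uses a pseudo-element).
    """

    reaction_id: str
    kind: str
    element: Optional[str] = None
    imbalance: Optional[float] = None


class MetabolicModel:
    """A genome-scale metabolic network.

    Parameters
    ----------
    metabolites, reactions
        Entity lists; ids must be unique within each.
    compartments
        Mapping compartment id -> display name.
    biomass_reaction_id
        Id of the growth pseudo-reaction (must exist in ``reactions``).
    """

    def __init__(
        self,
        model_id: str,
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        compartments: Mapping[str, str],
        biomass_reaction_id: Optional[str] = None,
    ):
        self.id = model_id
        self.metabolites: dict[str, Metabolite] = {}
        for met in metabolites:
            if met.id in self.metabolites:
                raise ModelValidationError(f"duplicate metabolite id {met.id!r}")
            self.metabolites[met.id] = met
        self.reactions: dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            self.reactions[rxn.id] = rxn
        self.compartments = dict(compartments)
        self.biomass_reaction_id = biomass_reaction_id

    # -- invariants ---------------------------------------------------------

    def validate(self, require_biomass: bool = True) -> None:
        """Check structural invariants; raise ModelValidationError on the first failure."""
        if not self.reactions:
            raise ModelValidationError("model has no reactions")
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelValidationError(
                    f"metabolite {met.id!r} references undeclared compartment "
                    f"{met.compartment!r}"
                )
        for rxn in self.reactions.values():
            if not rxn.stoichiometry:
                raise ModelValidationError(f"reaction {rxn.id!r} has empty stoichiometry")
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} has lower_bound > upper_bound"
                )
            if rxn.kind not in REACTION_KINDS:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} has unknown kind {rxn.kind!r}"
                )
            if rxn.kind == "exchange" and len(rxn.stoichiometry) != 1:
                raise ModelValidationError(
                    f"exchange reaction {rxn.id!r} must touch exactly one metabolite"
                )
            missing = [m for m in rxn.stoichiometry if m not in self.metabolites]
            if missing:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolite(s) "
                    + ", ".join(sorted(missing))
                )
        if require_biomass:
            if self.biomass_reaction_id is None:
                raise ModelValidationError("model has no biomass_reaction_id")
            if self.biomass_reaction_id not in self.reactions:
                raise ModelValidationError(
                    f"biomass reaction {self.biomass_reaction_id!r} not in model"
                )
        used = set()
        for rxn in self.reactions.values():
            used |= set(rxn.stoichiometry)
        orphan = set(self.metabolites) - used
        if orphan:
            raise ModelValidationError(
                "metabolite(s) not referenced by any reaction: "
                + ", ".join(sorted(orphan))
            )

    # -- derived views ------------------------------------------------------

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions.values():
            out |= rxn.genes
        return out

    @property
    def biomass_reaction(self) -> Reaction:
        if self.biomass_reaction_id is None:
            raise ModelValidationError("model has no biomass reaction")
        return self.reactions[self.biomass_reaction_id]

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def stoichiometric_matrix(self):
        """S as a dense numpy array (metabolites x reactions) plus row/col ids."""
        import numpy as np

        met_ids = list(self.metabolites)
        rxn_ids = list(self.reactions)
        met_index = {m: i for i, m in enumerate(met_ids)}
        S = np.zeros((len(met_ids), len(rxn_ids)))
        for j, rid in enumerate(rxn_ids):
            for mid, coef in self.reactions[rid].stoichiometry.items():
                S[met_index[mid], j] = coef
        return S, met_ids, rxn_ids

    def copy(self) -> "MetabolicModel":
        import copy as _copy

        return _copy.deepcopy(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        if (
            self.id != other.id
            or self.compartments != other.compartments
            or self.biomass_reaction_id != other.biomass_reaction_id
            or set(self.metabolites) != set(other.metabolites)
            or set(self.reactions) != set(other.reactions)
        ):
            return False
        for mid, met in self.metabolites.items():
            if met != other.metabolites[mid]:
                return False
        for rid, rxn in self.reactions.items():
            if rxn != other.reactions[rid]:
                return False
        return True

    def __repr__(self) -> str:
        return (
            f"<MetabolicModel {self.id}: {len(self.metabolites)} metabolites, "
            f"{len(self.reactions)} reactions>"
        )


# ---------------------------------------------------------------------------
# Quality checks and summaries
# ---------------------------------------------------------------------------

_BALANCE_EXEMPT_KINDS = frozenset({"exchange", "biomass", "demand"})


def check_balance(model: MetabolicModel, atol: float = 1e-9) -> list[BalanceIssue]:
    """Per-element mass balance of every non-pseudo reaction.

    For each reaction not of kind exchange/biomass/demand, computes the net
    elemental flux sum_m s_mr * count(element, formula_m) and reports every
    element whose sum is nonzero.  Reactions touching a metabolite without a
    formula, or one using pseudo-elements (R, X), are reported as
    ``unverifiable`` instead.  An empty list means every checkable reaction
    balances.  The check is order-independent and idempotent.
    """
    issues: list[BalanceIssue] = []
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        if rxn.kind in _BALANCE_EXEMPT_KINDS:
            continue
        totals: dict[str, float] = {}
        verifiable = True
        for mid, coef in rxn.stoichiometry.items():
            counts = model.metabolites[mid].element_counts()
            if counts is None or PSEUDO_ELEMENTS & set(counts):
                verifiable = False
                break
            for element, n in counts.items():
                totals[element] = totals.get(element, 0.0) + coef * n
        if not verifiable:
            issues.append(BalanceIssue(rid, "unverifiable"))
            continue
        for element in sorted(totals):
            if abs(totals[element]) > atol:
                issues.append(BalanceIssue(rid, "imbalanced", element, totals[element]))
    return issues


def model_summary(model: MetabolicModel) -> dict:
    """Count genes, reactions by kind and metabolites by compartment."""
    by_kind: dict[str, int] = {kind: 0 for kind in REACTION_KINDS}
    for rxn in model.reactions.values():
        by_kind[rxn.kind] = by_kind.get(rxn.kind, 0) + 1
    by_compartment = {cid: 0 for cid in model.compartments}
    for met in model.metabolites.values():
        by_compartment[met.compartment] = by_compartment.get(met.compartment, 0) + 1
    return {
        "model_id": model.id,
        "genes": len(model.genes),
        "reactions": len(model.reactions),
        "reactions_by_kind": by_kind,
        "metabolites": len(model.metabolites),
        "metabolites_by_compartment": by_compartment,
        "biomass_reaction_id": model.biomass_reaction_id,
    }
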