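"""Synthetic networks with planted ground truth.

The generator builds a stoichiometrically and elementally consistent toy
network shaped like a minimal heterotroph: one carbon substrate taken up
through an exchange/transport pair, a linear catabolic backbone, byproducts
split off the backbone (mass-balanced by formula subtraction) and secreted,
and a biomass reaction draining the terminal backbone metabolite plus
byproduct precursors.  Everything downstream of the generator is testable
against known answers:

* two planted steady-state flux vectors — the reference optimum and the
  perturbed state scaled by a known activity ratio — define condition-
  specific "truth";
* *consistent* gene signals sit on backbone reactions and report exactly the
  planted activity ratio; *contradictory* signals sit on flux-capped
  duplicate reactions whose bounds make the reported change impossible, so
  the expected maximum consistency score equals the consistent-signal count;
* metabolite signals report the planted production ratio of secreted
  byproducts;
* optional planted dead-end branches give known blocked reactions, with a
  repair reaction (plus decoys) in a universal database giving known
  minimal gap-fill sets.

Formulas are built over C/H/O/N so the elemental balance check is exercised
honestly; all outputs are deterministic functions of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction, parse_gpr
from .model import format_formula
from .omics import GeneRecord, MetaboliteRecord, OmicsData
from .remi import gene_candidate_id, metabolite_candidate_id
from .thermo import ThermoAnnotation, solve_fba


class SyntheticSpecError(ValueError):
    """Raised when a generator specification is internally unsatisfiable."""


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic instance.

    ``flux_ratio`` is the planted perturbed/reference activity ratio (0.25:
    the perturbed condition runs the backbone at a quarter of the reference
    rate, comfortably past the 2-fold differential-expression threshold).
    """

    n_metabolites: int = 20
    n_reactions: int = 30
    n_exchanges: int = 3
    n_consistent_gene_signals: int = 4
    n_inconsistent_gene_signals: int = 2
    n_metabolite_signals: int = 2
    n_blocked: int = 0
    noise_sd: float = 0.0
    seed: int = 1
    flux_ratio: float = 0.25
    uptake_rate: float = 10.0
    min_activity: float = 1e-3
    dg_metabolite_fraction: float = 0.76
    dg_reaction_fraction: float = 0.84

    def validate(self) -> None:
        W = self.n_exchanges - 1
        if W < 1:
            raise SyntheticSpecError("need at least 2 exchanges (substrate + byproduct)")
        if self.n_metabolite_signals > W:
            raise SyntheticSpecError(
                f"{self.n_metabolite_signals} metabolite signals but only {W} byproducts"
            )
        L = self.n_metabolites - 2 - 2 * W - self.n_blocked
        if L < self.n_consistent_gene_signals + 2:
            raise SyntheticSpecError(
                "backbone too short for the requested consistent signals; "
                "increase n_metabolites"
            )
        if L <= W:
            raise SyntheticSpecError("backbone too short for byproduct branch points")
        n_dup = (
            self.n_reactions
            - 3
            - L
            - 2 * W
            - self.n_blocked
            - self.n_inconsistent_gene_signals
        )
        if n_dup < 0:
            raise SyntheticSpecError(
                "n_reactions too small for this metabolite/signal budget"
            )
        if not (0 < self.flux_ratio < 1 / 2 or self.flux_ratio > 2):
            raise SyntheticSpecError(
                "flux_ratio must clear the 2-fold threshold on one side"
            )
        if self.uptake_rate <= 0:
            raise SyntheticSpecError("uptake_rate must be > 0")

    @property
    def n_byproducts(self) -> int:
        return self.n_exchanges - 1

    @property
    def chain_length(self) -> int:
        return self.n_metabolites - 2 - 2 * self.n_byproducts - self.n_blocked


@dataclass
class GroundTruth:
    blocked_reactions: set[str] = field(default_factory=set)
    gapfill_sets: dict[str, list[str]] = field(default_factory=dict)
    candidate_labels: dict[str, str] = field(default_factory=dict)
    expected_mcs: int = 0
    planted_growth_ratio: float = 1.0
    v_reference: dict[str, float] = field(default_factory=dict)
    v_perturbed: dict[str, float] = field(default_factory=dict)
    signal_genes: dict[str, str] = field(default_factory=dict)
    universal_db: Optional[MetabolicModel] = None

    @property
    def consistent_candidates(self) -> set[str]:
        return {c for c, lab in self.candidate_labels.items() if lab == "consistent"}


#: Byproduct unit formulas subtracted from the backbone (small C/H/O/N units).
_BYPRODUCT_UNITS = [
    {"C": 1, "H": 2, "O": 1},
    {"N": 1, "H": 3},
    {"C": 1, "H": 4},
    {"C": 1, "O": 2},
    {"H": 2, "O": 1},
]


def _sub_formula(a: dict[str, int], b: dict[str, int]) -> dict[str, int]:
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) - n
        if out[el] < 0:
            raise SyntheticSpecError("backbone formula underflow")
    return {el: n for el, n in out.items() if n}


def generate_toy_model(
    spec: SyntheticSpec,
) -> tuple[MetabolicModel, ThermoAnnotation, GroundTruth]:
    """Build one synthetic instance; deterministic in ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    W = spec.n_byproducts
    B = spec.n_blocked
    L = spec.chain_length
    alpha = spec.flux_ratio
    U = spec.uptake_rate

    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    units = [_BYPRODUCT_UNITS[j % len(_BYPRODUCT_UNITS)] for j in range(W)]
    start: dict[str, int] = {"C": 10, "H": 20, "O": 10, "N": 5}
    for unit in units:
        for el, n in unit.items():
            start[el] = start.get(el, 0) + n

    def met(mid, comp, formula):
        mets.append(Metabolite(id=mid, compartment=comp, formula=formula))
        return mid

    start_str = format_formula(start)
    met("s_e", "e", start_str)
    met("s_c", "c", start_str)
    # backbone metabolites: emissions happen on the last W steps
    emission_steps = set(range(L - W + 1, L + 1))
    formula = dict(start)
    chain_formulas = []
    for i in range(1, L + 1):
        if i in emission_steps:
            formula = _sub_formula(formula, units[i - (L - W + 1)])
        chain_formulas.append(dict(formula))
        met(f"m{i}", "c", format_formula(formula))
    for j in range(W):
        unit_str = format_formula(units[j])
        met(f"byp{j + 1}_c", "c", unit_str)
        met(f"byp{j + 1}_e", "e", unit_str)
    branch = L - W  # dead-end branch point, outside the signal region
    for k in range(1, B + 1):
        met(f"dead{k}_c", "c", format_formula(chain_formulas[branch - 1]))

    gene_counter = [0]

    def gene() -> str:
        gene_counter[0] += 1
        return f"g{gene_counter[0]:03d}"

    rxns.append(
        Reaction("EX_s", {"s_e": -1.0}, lower_bound=-U, upper_bound=0.0, kind="exchange")
    )
    rxns.append(
        Reaction(
            "T_s",
            {"s_e": -1.0, "s_c": 1.0},
            lower_bound=0.0,
            kind="transport",
            gpr=parse_gpr(gene()),
        )
    )
    signal_steps = list(range(2, 2 + spec.n_consistent_gene_signals))
    signal_genes: dict[str, str] = {}
    for i in range(1, L + 1):
        sub = "s_c" if i == 1 else f"m{i - 1}"
        stoich = {sub: -1.0, f"m{i}": 1.0}
        if i in emission_steps:
            stoich[f"byp{i - (L - W + 1) + 1}_c"] = 1.0
        g = gene()
        if i in signal_steps:
            rule = g  # single gene keeps the planted ratio exact
        else:
            # vary GPR shapes across seeds: isozymes or complexes
            shape = rng.integers(0, 3)
            rule = g if shape == 0 else f"{g} {'or' if shape == 1 else 'and'} {gene()}"
        rxn = Reaction(
            f"R{i:02d}", stoich, lower_bound=0.0, kind="metabolic", gpr=parse_gpr(rule)
        )
        rxns.append(rxn)
        if i in signal_steps:
            signal_genes[rxn.id] = g
    for j in range(W):
        rxns.append(
            Reaction(
                f"T_byp{j + 1}",
                {f"byp{j + 1}_c": -1.0, f"byp{j + 1}_e": 1.0},
                lower_bound=0.0,
                kind="transport",
                gpr=parse_gpr(gene()),
            )
        )
        rxns.append(
            Reaction(
                f"EX_byp{j + 1}",
                {f"byp{j + 1}_e": -1.0},
                lower_bound=0.0,
                kind="exchange",
            )
        )
    blocked_ids: list[str] = []
    for k in range(1, B + 1):
        sub = f"m{branch}" if k == 1 else f"dead{k - 1}_c"
        rxns.append(
            Reaction(
                f"D{k:02d}",
                {sub: -1.0, f"dead{k}_c": 1.0},
                lower_bound=0.0,
                kind="metabolic",
                gpr=parse_gpr(gene()),
            )
        )
        blocked_ids.append(f"D{k:02d}")
    # contradictory-signal reactions: flux-capped duplicates of backbone step 1
    contradict_ids = []
    for j in range(spec.n_inconsistent_gene_signals):
        g = gene()
        rid = f"I{j + 1:02d}"
        rxns.append(
            Reaction(
                rid,
                {"s_c": -1.0, "m1": 1.0},
                lower_bound=0.0,
                upper_bound=2.0 * spec.min_activity,
                kind="metabolic",
                gpr=parse_gpr(g),
            )
        )
        signal_genes[rid] = g
        contradict_ids.append(rid)
    # filler duplicates of non-signal backbone steps (parallel isoenzymes)
    n_dup = (
        spec.n_reactions - 3 - L - 2 * W - B - spec.n_inconsistent_gene_signals
    )
    dup_steps = [i for i in range(1, L + 1) if i not in signal_steps]
    for j in range(n_dup):
        i = dup_steps[j % len(dup_steps)]
        sub = "s_c" if i == 1 else f"m{i - 1}"
        stoich = {sub: -1.0, f"m{i}": 1.0}
        if i in emission_steps:
            stoich[f"byp{i - (L - W + 1) + 1}_c"] = 1.0
        rxns.append(
            Reaction(
                f"R{i:02d}_iso{j + 1}",
                stoich,
                lower_bound=0.0,
                kind="metabolic",
                gpr=parse_gpr(gene()),
            )
        )
    # biomass drains the terminal metabolite plus byproduct precursors;
    # byproduct demand stays below the 1:1 emission yield so growth is
    # substrate-limited in every instance
    biomass_stoich: dict[str, float] = {
        f"m{L}": -1.0,
        "byp1_c": -round(float(rng.uniform(0.05, 0.2)), 3),
    }
    if W >= 2:
        biomass_stoich["byp2_c"] = -round(float(rng.uniform(0.02, 0.1)), 3)
    rxns.append(
        Reaction("BIOMASS", biomass_stoich, lower_bound=0.0, kind="biomass")
    )

    model = MetabolicModel(
        model_id=f"synthetic_seed{spec.seed}",
        metabolites=mets,
        reactions=rxns,
        compartments={"c": "cytosol", "e": "extracellular"},
        biomass_reaction_id="BIOMASS",
    )
    model.validate()

    thermo = _build_thermo(spec, model, L, W, rng)
    truth = _build_truth(spec, model, signal_genes, blocked_ids, branch, L, W)
    return model, thermo, truth


def _build_thermo(
    spec: SyntheticSpec, model: MetabolicModel, L: int, W: int, rng
) -> ThermoAnnotation:
    """Formation energies descending along the backbone (every step exergonic)
    and direct reaction energies for a fraction of eligible reactions."""
    thermo = ThermoAnnotation()
    ordered = (
        [f"m{i}" for i in range(1, L + 1)]
        + ["s_c", "s_e"]
        + [f"byp{j + 1}_{c}" for j in range(W) for c in ("c", "e")]
        + [m for m in model.metabolites if m.startswith("dead")]
    )
    n_met = math.ceil(spec.dg_metabolite_fraction * len(model.metabolites))
    for mid in ordered[:n_met]:
        if mid.startswith("m"):
            thermo.dGf_std[mid] = -5.0 * int(mid[1:])
        elif mid.startswith("s"):
            thermo.dGf_std[mid] = 0.0
        elif mid.startswith("byp"):
            thermo.dGf_std[mid] = -2.0
        else:  # dead-end isomers, slightly downhill along the branch
            k = int(mid[4:].split("_")[0])
            branch = L - W
            thermo.dGf_std[mid] = -5.0 * branch - 1.0 * k
    eligible = sorted(
        rid
        for rid, r in model.reactions.items()
        if r.kind in ("metabolic", "transport")
    )
    n_rxn = math.ceil(spec.dg_reaction_fraction * len(eligible))
    for rid in eligible[:n_rxn]:
        # every annotated step exergonic in its planted forward direction
        thermo.dGr_std[rid] = -float(rng.integers(5, 20))
    return thermo


def _build_truth(
    spec: SyntheticSpec,
    model: MetabolicModel,
    signal_genes: dict[str, str],
    blocked_ids: list[str],
    branch: int,
    L: int,
    W: int,
) -> GroundTruth:
    truth = GroundTruth()
    truth.signal_genes = signal_genes
    truth.blocked_reactions = set(blocked_ids)
    truth.planted_growth_ratio = spec.flux_ratio

    ref = solve_fba(model)
    if not ref.ok or ref.objective_value is None or ref.objective_value <= 0:
        raise SyntheticSpecError("generated model is not viable (FBA growth <= 0)")
    truth.v_reference = dict(ref.fluxes)
    truth.v_perturbed = {
        rid: spec.flux_ratio * v for rid, v in ref.fluxes.items()
    }

    for rid in signal_genes:
        label = "contradictory" if rid.startswith("I") else "consistent"
        truth.candidate_labels[gene_candidate_id(rid)] = label
    for j in range(spec.n_metabolite_signals):
        truth.candidate_labels[metabolite_candidate_id(f"byp{j + 1}_e")] = "consistent"
    truth.expected_mcs = sum(
        1 for lab in truth.candidate_labels.values() if lab == "consistent"
    )

    if blocked_ids:
        db = _build_repair_db(model, blocked_ids, branch)
        truth.universal_db = db
        truth.gapfill_sets[blocked_ids[0]] = ["UDB_repair"]
    return truth


def _build_repair_db(
    model: MetabolicModel, blocked_ids: list[str], branch: int
) -> MetabolicModel:
    """Universal db: one repair closing the dead-end branch, plus decoys."""
    last_dead = model.reactions[blocked_ids[-1]]
    dead_met = next(m for m, c in last_dead.stoichiometry.items() if c > 0)
    target = f"m{branch}"
    db_mets = [
        model.metabolites[dead_met],
        model.metabolites[target],
        Metabolite("decoyA_c", "c", formula="CH4"),
        Metabolite("decoyB_c", "c", formula="CH4"),
    ]
    db_rxns = [
        Reaction(
            "UDB_repair",
            {dead_met: -1.0, target: 1.0},
            lower_bound=0.0,
            kind="metabolic",
            gpr=parse_gpr("gdb001"),
        ),
        Reaction(
            "UDB_decoy1",
            {"decoyA_c": -1.0, "decoyB_c": 1.0},
            lower_bound=0.0,
            kind="metabolic",
            gpr=parse_gpr("gdb002"),
        ),
        Reaction(
            "UDB_decoy2",
            {dead_met: -1.0, "decoyA_c": 1.0},
            lower_bound=0.0,
            kind="metabolic",
            gpr=parse_gpr("gdb003"),
        ),
    ]
    db = MetabolicModel(
        model_id="universal_db",
        metabolites=db_mets,
        reactions=db_rxns,
        compartments=dict(model.compartments),
    )
    db.validate(require_biomass=False)
    return db


def generate_condition_omics(
    model: MetabolicModel, truth: GroundTruth, spec: SyntheticSpec
) -> OmicsData:
    """Derive expression/abundance tables from the planted flux states.

    Consistent gene signals report the planted per-reaction activity ratio
    (plus Gaussian noise on the log2 scale); contradictory signals report the
    inverted ratio.  Metabolite signals report the planted byproduct
    production ratio.  FDR assignment is deterministic: signal genes get
    0.01, background genes 0.5, so differential-expression selection is a
    pure threshold gate.
    """
    rng = np.random.default_rng(spec.seed + 104729)  # decoupled noise stream
    omics = OmicsData()
    log2_alpha = math.log2(spec.flux_ratio)
    for rid, gid in sorted(truth.signal_genes.items()):
        if rid.startswith("I"):
            lfc = -log2_alpha
        else:
            lfc = log2_alpha
        if spec.noise_sd > 0:
            lfc += rng.normal(0.0, spec.noise_sd)
        omics.gene_records[gid] = GeneRecord(gid, lfc, 0.01)
    signal_gene_ids = set(omics.gene_records)
    for gid in sorted(model.genes - signal_gene_ids):
        lfc = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        omics.gene_records[gid] = GeneRecord(gid, lfc, 0.5)
    for j in range(spec.n_metabolite_signals):
        lfc = log2_alpha
        if spec.noise_sd > 0:
            lfc += rng.normal(0.0, spec.noise_sd)
        mid = f"byp{j + 1}_e"
        omics.metabolite_records[mid] = MetaboliteRecord(mid, 2.0 ** lfc, True)
    return omics


# ---------------------------------------------------------------------------
# Topological replicas of the two curated gap-fill case studies
# ---------------------------------------------------------------------------


def fixture_fig3_pathways() -> tuple[MetabolicModel, MetabolicModel, MetabolicModel]:
    """(toluene-route fixture, phenylalanine-route fixture, universal db).

    Topological replicas with unit stoichiometry and no formulas (the
    published pathway diagrams fix the wiring, not balanced equations):

    * the toluene fixture has a working degradation route to central carbon
      metabolism plus a second route whose CoA-transferase step
      (EC 2.8.3.6) is missing, leaving that whole route blocked — one
      database reaction unblocks it;
    * the phenylalanine fixture misses three steps (EC 4.1.1.28 phenylalanine
      decarboxylase, EC 1.14.14.54 toward 2-hydroxyphenylacetate — a
      metabolite absent from the fixture model — and the EC 1.14.13.-
      homogentisate-forming step), so the minimal fill has size three;
    * the shared universal database carries the missing steps plus decoys
      that no minimal solution selects.
    """
    tol = _toluene_fixture()
    phe = _phe_fixture()
    db = _fig3_universal_db()
    return tol, phe, db


def _toluene_fixture() -> MetabolicModel:
    mets = [
        Metabolite("tol_e", "e"),
        Metabolite("tol_c", "c"),
        Metabolite("mcat_c", "c", name="3-methylcatechol"),
        Metabolite("i1_c", "c"),
        Metabolite("i2_c", "c"),
        Metabolite("i3_c", "c"),
        Metabolite("pyr_c", "c", name="pyruvate"),
        Metabolite("succ_c", "c", name="succinate"),
        Metabolite("q1_c", "c"),
        Metabolite("q2_c", "c"),
        Metabolite("q3_c", "c"),
        Metabolite("q4_c", "c"),
    ]
    rxns = [
        Reaction("EX_tol", {"tol_e": -1.0}, lower_bound=-10.0, upper_bound=0.0, kind="exchange"),
        Reaction("T_tol", {"tol_e": -1.0, "tol_c": 1.0}, lower_bound=0.0, kind="transport", gpr=parse_gpr("gtolT")),
        Reaction("TOLDO", {"tol_c": -1.0, "mcat_c": 1.0}, lower_bound=0.0, gpr=parse_gpr("gtdo1 and gtdo2")),
        # main (functional) route to pyruvate
        Reaction("M1", {"mcat_c": -1.0, "i1_c": 1.0}, lower_bound=0.0, ec_numbers=["1.13.11.2"], gpr=parse_gpr("gm1")),
        Reaction("M2", {"i1_c": -1.0, "i2_c": 1.0}, lower_bound=0.0, ec_numbers=["3.7.1.-"], gpr=parse_gpr("gm2")),
        Reaction("M3", {"i2_c": -1.0, "i3_c": 1.0}, lower_bound=0.0, ec_numbers=["4.2.1.8"], gpr=parse_gpr("gm3")),
        Reaction("M4", {"i3_c": -1.0, "pyr_c": 1.0}, lower_bound=0.0, ec_numbers=["4.1.3.39"], gpr=parse_gpr("gm4")),
        Reaction("PYRSUC", {"pyr_c": -1.0, "succ_c": 1.0}, lower_bound=0.0, gpr=parse_gpr("gtca")),
        # second route, disconnected by the missing CoA transferase; six
        # genes along the route, three of them differentially expressed
        Reaction("S1", {"mcat_c": -1.0, "q1_c": 1.0}, lower_bound=0.0, gpr=parse_gpr("gr1")),
        Reaction("S2", {"q1_c": -1.0, "q2_c": 1.0}, lower_bound=0.0, gpr=parse_gpr("gr2 and gr2b")),
        Reaction("S4", {"q3_c": -1.0, "q4_c": 1.0}, lower_bound=0.0, gpr=parse_gpr("gr4")),
        Reaction("S5", {"q4_c": -1.0, "succ_c": 1.0}, lower_bound=0.0, gpr=parse_gpr("gr5 or gr5b")),
        Reaction("BIOMASS", {"pyr_c": -1.0, "succ_c": -0.5}, lower_bound=0.0, kind="biomass"),
    ]
    model = MetabolicModel(
        "fig_toluene", mets, rxns, {"c": "cytosol", "e": "extracellular"}, "BIOMASS"
    )
    model.validate()
    return model


def _phe_fixture() -> MetabolicModel:
    mets = [
        Metabolite("x_e", "e"),
        Metabolite("x_c", "c"),
        Metabolite("phe_e", "e", name="L-phenylalanine"),
        Metabolite("phe_c", "c", name="L-phenylalanine"),
        Metabolite("pea_c", "c", name="phenethylamine"),
        Metabolite("pald_c", "c", name="phenylacetaldehyde"),
        Metabolite("hgt_c", "c", name="homogentisate"),
        Metabolite("mfum_c", "c", name="maleylacetoacetate"),
        Metabolite("faa_c", "c", name="fumarylacetoacetate"),
        Metabolite("fum_c", "c", name="fumarate"),
        Metabolite("oaa_c", "c", name="oxaloacetate"),
    ]
    rxns = [
        # a working carbon source keeps biomass feasible without the route
        Reaction("EX_x", {"x_e": -1.0}, lower_bound=-10.0, upper_bound=0.0, kind="exchange"),
        Reaction("T_x", {"x_e": -1.0, "x_c": 1.0}, lower_bound=0.0, kind="transport", gpr=parse_gpr("gxT")),
        Reaction("XOAA", {"x_c": -1.0, "oaa_c": 1.0}, lower_bound=0.0, gpr=parse_gpr("gxf")),
        Reaction("EX_phe", {"phe_e": -1.0}, lower_bound=-10.0, upper_bound=0.0, kind="exchange"),
        Reaction("T_phe", {"phe_e": -1.0, "phe_c": 1.0}, lower_bound=0.0, kind="transport", gpr=parse_gpr("gpheT")),
        # present route steps (their upstream/downstream links are missing)
        Reaction("E1", {"pea_c": -1.0, "pald_c": 1.0}, lower_bound=0.0, gpr=parse_gpr("ge1")),
        Reaction("E2", {"hgt_c": -1.0, "mfum_c": 1.0}, lower_bound=0.0, gpr=parse_gpr("ge2")),
        Reaction("E3", {"mfum_c": -1.0, "faa_c": 1.0}, lower_bound=0.0, gpr=parse_gpr("ge3")),
        Reaction("E4", {"faa_c": -1.0, "fum_c": 1.0}, lower_bound=0.0, gpr=parse_gpr("ge4")),
        Reaction("E5", {"fum_c": -1.0, "oaa_c": 1.0}, lower_bound=0.0, gpr=parse_gpr("ge5")),
        Reaction("BIOMASS", {"oaa_c": -1.0}, lower_bound=0.0, kind="biomass"),
    ]
    model = MetabolicModel(
        "fig_phenylalanine", mets, rxns, {"c": "cytosol", "e": "extracellular"}, "BIOMASS"
    )
    model.validate()
    return model


def _fig3_universal_db() -> MetabolicModel:
    mets = [
        Metabolite("q2_c", "c"),
        Metabolite("q3_c", "c"),
        Metabolite("phe_c", "c"),
        Metabolite("pea_c", "c"),
        Metabolite("pald_c", "c"),
        Metabolite("hpa_c", "c", name="2-hydroxyphenylacetate"),
        Metabolite("hgt_c", "c"),
        Metabolite("mcat_c", "c"),
        Metabolite("dz1_c", "c"),
        Metabolite("dz2_c", "c"),
        Metabolite("dz3_c", "c"),
    ]
    rxns = [
        Reaction("GF_2836", {"q2_c": -1.0, "q3_c": 1.0}, lower_bound=0.0, ec_numbers=["2.8.3.6"], gpr=parse_gpr("scoA")),
        Reaction("GF_41128", {"phe_c": -1.0, "pea_c": 1.0}, lower_bound=0.0, ec_numbers=["4.1.1.28"]),
        Reaction("GF_1141454", {"pald_c": -1.0, "hpa_c": 1.0}, lower_bound=0.0, ec_numbers=["1.14.14.54"], gpr=parse_gpr("CYP504")),
        Reaction("GF_11413", {"hpa_c": -1.0, "hgt_c": 1.0}, lower_bound=0.0, ec_numbers=["1.14.13.-"]),
        # decoys: dangling or disconnected conversions
        Reaction("GF_decoy1", {"dz1_c": -1.0, "dz2_c": 1.0}, lower_bound=0.0),
        Reaction("GF_decoy2", {"mcat_c": -1.0, "dz1_c": 1.0}, lower_bound=0.0),
        Reaction("GF_decoy3", {"q2_c": -1.0, "dz3_c": 1.0}, lower_bound=0.0),
        Reaction("GF_decoy4", {"pald_c": -1.0, "dz3_c": 1.0}, lower_bound=0.0),
    ]
    db = MetabolicModel(
        "fig_universal_db", mets, rxns, {"c": "cytosol"}, None
    )
    db.validate(require_biomass=False)
    return db


def fixture_fig3_omics() -> tuple[OmicsData, OmicsData]:
    """(toluene omics, phenylalanine omics) supporting the blocked routes:
    three differentially expressed genes on the toluene route and four
    measured exometabolites touching the phenylalanine route."""
    tol = OmicsData(
        gene_records={
            "gr1": GeneRecord("gr1", 2.1, 0.001),
            "gr2": GeneRecord("gr2", 1.6, 0.004),
            "gr2b": GeneRecord("gr2b", -1.8, 0.02),
            "gm1": GeneRecord("gm1", 0.2, 0.6),
        }
    )
    phe = OmicsData(
        metabolite_records={
            "hgt": MetaboliteRecord("hgt", 2.5, True),
            "mfum": MetaboliteRecord("mfum", 3.1, True),
            "faa": MetaboliteRecord("faa", 2.0, True),
            "fum": MetaboliteRecord("fum", 0.4, True),
        }
    )
    return tol, phe
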