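# Methods

This note documents the models and procedures implemented in `remiflux`,
their assumptions, the tunable parameters with defaults, the synthetic
study conditions, and the numerical choices that matter.

## Flux analysis

**FBA.** Fluxes are split as v = f − b with f, b ≥ 0; a positive lower
bound on v becomes a lower bound on f, a negative upper bound mirrors onto
b. Steady state `S·v = 0` and bounds define the polytope; the objective
(biomass unless stated otherwise) is maximized with HiGHS through
`scipy.optimize.milp`. Flux bounds default to ±1000 mmol·gDW⁻¹·h⁻¹ when a
file omits them (community convention).

**TFA.** For every reaction r of kind metabolic/transport whose standard
Gibbs energy is known — directly as Δ_r G'°, or derived as Σ_m s_mr·Δ_f G°_m
when every participant has a formation energy (direct values take
precedence) — the transformed reaction energy is a variable tied to
log-concentration variables:

    ΔG_r = Δ_rG'° + R·T · Σ_m s_mr ln c_m       (variable-activity species)

and coupled to direction binaries u⁺, u⁻:

    u⁺ + u⁻ ≤ 1,  f ≤ M·u⁺,  b ≤ M·u⁻,
    ΔG_r ≤ −δ + K(1−u⁺),   −ΔG_r ≤ −δ + K(1−u⁻).

Boundary pseudo-reactions (exchange, demand, biomass) never carry
thermodynamic constraints, and reactions with incomplete Gibbs data keep
their flux bounds only — constraints are only ever *added*, so the TFA
optimum is bounded above by the FBA optimum and equals it when the
annotation is empty (both properties are tested).

Defaults: concentration bounds 10⁻⁷–10⁻¹ mol·L⁻¹ (physiological range,
overridable per metabolite); T = 303.15 K (30 °C cultures);
R = 8.314×10⁻³ kJ·mol⁻¹·K⁻¹; δ = 0 (the strict inequality is relaxed to ≤
at solver tolerance); M = 1000 matching the flux bounds; K = 10⁵ kJ·mol⁻¹.
Protons, water and hydroxide are treated at fixed activity and excluded
from the ln-concentration sum (matched on the compartment-stripped id:
h, h2o, oh, proton, water). With the default bounds the concentration term
spans ±RT·ln(10⁶) ≈ ±34.8 kJ·mol⁻¹, so a Δ_r G'° of +50 kJ·mol⁻¹ is
genuinely sign-forcing while +20 is not — both cases are tested.

**FVA / blocked reactions.** Flux variability at objective fraction γ
re-solves min/max per reaction after pinning objective ≥ γ·optimum;
fraction 0 probes absolute capability. A reaction is *blocked* iff its
fraction-0 range is (0, 0) with every exchange opened to ±1000; the
detection is independent of objective choice, reaction order and uniform
bound scaling (tested against a direct per-reaction LP oracle).

**Uptake estimation.** The minimal uptake magnitude supporting a target
growth is found by fixing biomass ≥ target and minimizing f+b of the named
exchange; an unreachable target returns an explicit None.

## Network decomposition and gap-filling

Decomposition takes connected components of the bipartite
reaction–metabolite graph after removing currency metabolites (ATP, ADP,
AMP, NAD(P)(H), H⁺, H₂O, Pi, PPi, CO₂, CoA by compartment-stripped id;
configurable). The currency list affects decomposition only, never flux
arithmetic. Components are ordered by reaction count descending, the
largest flagged as the main subnetwork. A blocked *pathway* is a maximal
connected group of blocked reactions in that bipartite sense — note that a
route interrupted by a missing enzyme therefore decomposes into the
fragments on either side of the gap.

Blocked pathways are prioritized by omics support: the number of
significantly differentially expressed genes (FDR < 0.05 and
|log2 FC| ≥ 1, i.e. fold-change > 2) in the group's GPRs plus the number
of measured metabolites among its participants; unsupported groups are
dropped.

Gap-filling merges the model with a universal reaction database, gates
every database reaction j behind a binary y_j (f_j ≤ ub·y_j, b_j ≤ −lb·y_j;
database reactions are assumed relaxed, lb ≤ 0 ≤ ub), requires the target
reaction to carry ≥ ε_gf = 10⁻³ mmol·gDW⁻¹·h⁻¹ (forward, or backward for a
reversible target — the cheaper direction wins), or a transient demand when
the target is a metabolite, and minimizes Σy. Exchanges are opened for the
probe, consistent with blocked detection. Equal-size alternative sets are
enumerated with integer cuts. Minimality is certified against exhaustive
subset search in the tests for databases of ≤ 8 candidates.

## Two-condition consistency maximization

One MILP holds a reference and a perturbed copy of the model (split
fluxes, steady state, bounds, and TFA coupling per copy when an annotation
is supplied). Candidate constraints come from:

* **Gene expression** (variants `tgex`, `tgexm`): genes passing the DE gate
  are aggregated per reaction through the GPR with AND = min, OR = max
  (reference expression normalized to 1, perturbed to the ratio); the
  reaction becomes an up/down candidate when the aggregate ratio clears
  θ = 2 (or 1/θ). One candidate per regulated reaction.
* **Exometabolites** (variants `tm`, `tgexm`): each significantly changed
  metabolite constrains its total producing-side turnover
  P_m = Σ_{producing half-reactions} |s_mr|·(f or b), not net exchange,
  because a secreted metabolite may simultaneously be consumed.

Each candidate's binary z activates its big-M constraint pair (receiver ≥
ratio × donor; donor ≥ ε); the big-M is computed per constraint from the
donor-side bound, keeping numerics tight. Ratios are capped at
ρ_max = 100, ε = 10⁻³. The objective maximizes Σz; TMCS is the candidate
count (a second tally counting distinct source genes plus metabolites is
also reported, since either bookkeeping is defensible), MCS the optimum.
The MILP runs single-threaded with a 10⁻⁶ relative gap, so reruns are
deterministic.

A growth floor γ·(per-condition TFA max) is available but defaults to
γ = 0 (feasibility only): growth is deliberately a *post-hoc* maximization
with the indicators pinned to an active set, reported per condition and
(across alternatives) as mean ± sd. A hard floor would contradict
near-arrest phenotypes where the perturbed condition grows at ~1% of the
reference.

Alternative optima: Σz = MCS is pinned and each found active set Z adds
the cut Σ_{i∈Z} z_i ≤ MCS − 1 until infeasibility or the cap (default 40).
Completeness is tested against brute-force enumeration of all feasible
size-MCS subsets. The intersection/symmetric-difference of the
alternatives gives the common and varying constraints, labeled by source.
The *representative* alternative minimizes the L1 distance between its
biomass-precursor production vector (both conditions concatenated) and the
element-wise median vector over alternatives, ties broken by first index.

## Biomass building blocks

Precursors are the negative-coefficient substrates of the biomass
reaction, grouped by a configurable table over the standard biochemical
classes (amino acids, RNA/DNA nucleotides, cofactors and vitamins, lipids,
carbohydrates, minerals); unmapped precursors fall into `unclassified`
with a warning. Production ceilings use transient irreversible demand
sinks (bounds [0, 1000], closed when not probed): unconstrained against a
plain (T)FA model, or inside the two-condition problem with an active set
pinned, in which case the ceiling can only shrink (tested). Fold-changes
between conditions come from the representative alternative; the
cross-alternative p-value per precursor is a two-sided Wilcoxon
signed-rank test over paired per-alternative productions (a pragmatic
choice — the test is a knob, and with fewer than two alternatives p-values
are marked unavailable). Pathway deregulation tallies count common
constraints per annotated pathway, multi-pathway items once per pathway,
unannotated items under `unannotated`.

## Synthetic study conditions

The generator emulates the full input bundle — model, thermodynamic
annotation, and two-condition expression/metabolite tables — as a minimal
heterotroph: an uptake-limited substrate (default 10 mmol·gDW⁻¹·h⁻¹)
feeds a linear catabolic backbone; mass-balanced byproducts split off the
last backbone steps by formula subtraction (formulas over C/H/O/N, so
elemental balancing is exercised honestly) and are secreted; biomass
drains the terminal metabolite plus small byproduct shares (coefficients
drawn per seed from 0.05–0.2 and 0.02–0.1, always below the 1:1 emission
yield so growth stays substrate-limited). Default size: 20 metabolites /
30 reactions / 3 exchanges, with extra isoenzyme duplicates padding the
reaction count on non-signal steps.

Planted truth: the reference flux state is the FBA optimum; the perturbed
state is the same vector scaled by the planted activity ratio α = 0.25
(safely past the 2-fold DE threshold). *Consistent* gene signals sit on
single-gene backbone steps and report log2 α; *contradictory* signals sit
on flux-capped duplicate reactions (upper bound 2ε) whose reported
direction is physically impossible, so the expected MCS equals the
consistent-signal count and the unique optimal active set is exactly the
consistent candidates. Metabolite signals report the planted byproduct
production ratio. FDRs are assigned deterministically (0.01 for signals,
0.5 for background) so DE selection is a pure threshold gate; optional
Gaussian noise acts on the log2 scale. Gibbs energies are planted
exergonic along the planted directions (formation energies descending
along the backbone; direct reaction energies −5…−20 kJ·mol⁻¹) at coverage
fractions defaulting to 0.76 of metabolites and 0.84 of eligible
reactions. Optional dead-end branches plant known blocked reactions, with
a one-reaction repair plus decoys in a universal database.

The curated-route fixtures are topological replicas with unit
stoichiometry and no formulas (pathway wiring is what the diagrams fix,
not balanced equations): a toluene-degradation fixture whose second route
misses its CoA-transferase step (EC 2.8.3.6; minimal fill size 1, four
route reactions blocked, three DE genes along the route) and a
phenylalanine fixture missing three steps (EC 4.1.1.28, EC 1.14.14.54
toward 2-hydroxyphenylacetate — a metabolite absent from the fixture
model — and the EC 1.14.13.- homogentisate-forming step; minimal fill
size 3), plus a shared database with decoys that no minimal solution
selects.

What the synthetic data does *not* emulate: genome-scale size and
redundancy, noisy FDR estimation, compartment-specific thermodynamics,
cofactor coupling, and measurement missingness. Passing tests therefore
certify the algorithms (scores, minimality, enumeration completeness,
determinism, planted recovery) — not predictive accuracy on any real
organism.

## Numerical choices and determinism

All LP/MILPs run on HiGHS via scipy, single-threaded, relative MIP gap
10⁻⁶; indicator values are read at the 0.5 threshold. Blocked-detection
tolerance 10⁻⁶; steady state holds to solver feasibility tolerance
(≈10⁻⁹, asserted on planted states). Pipeline reports exclude wall-clock
timings (they live in a sidecar event log) and hash only the scientific
configuration, so a rerun with the same config and seed is byte-identical.
Problem sizes throughout the suite (20–35 reactions, ≤ 12 candidate
constraints, ≤ 8 database candidates) are chosen so every brute-force
oracle remains exhaustively enumerable.

## Known limitations

* The SBML round trip normalizes an absent metabolite charge to 0 (cobra's
  fbc writer); JSON and TSV round-trip exactly.
* Metabolite candidates for species produced by no reaction are skipped
  with a warning rather than counted as automatically violated.
* Gap-filling assumes database reactions are relaxed (lb ≤ 0 ≤ ub); a
  database reaction with a strictly positive lower bound would not be
  gateable by its indicator.
* The direction-pattern TFA oracle (tests) scales as 3^k and is only used
  with small covered sets; the MILP itself has no such limit.
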