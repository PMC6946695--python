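"""FBA, TFA and FVA against hand-computable chains and independent oracles."""

import math

import pytest

from remiflux.model import MetabolicModel, Metabolite, Reaction
from remiflux.synthetic import SyntheticSpec, generate_toy_model
from remiflux.thermo import (
    TFASettings,
    ThermoAnnotation,
    estimate_uptake_for_growth,
    flux_variability,
    load_thermo_tsv,
    solve_fba,
    solve_tfa,
    write_thermo_tsv,
)

from oracles import fba_oracle, fva_oracle, tfa_direction_enumeration


class TestFBA:
    def test_bound_limited_chain(self, chain_model):
        sol = solve_fba(chain_model)
        assert sol.ok
        assert sol.objective_value == pytest.approx(10.0)

    def test_half_yield_chain(self, chain_half_yield):
        assert solve_fba(chain_half_yield).objective_value == pytest.approx(5.0)

    def test_steady_state_and_bounds_hold(self, chain_model):
        sol = solve_fba(chain_model)
        S, met_ids, rxn_ids = chain_model.stoichiometric_matrix()
        v = [sol.fluxes[r] for r in rxn_ids]
        for i, mid in enumerate(met_ids):
            assert sum(S[i, j] * v[j] for j in range(len(v))) == pytest.approx(0, abs=1e-7)
        for rid in rxn_ids:
            rxn = chain_model.reactions[rid]
            assert rxn.lower_bound - 1e-7 <= sol.fluxes[rid] <= rxn.upper_bound + 1e-7

    @pytest.mark.parametrize("seed", [1, 2, 3, 11, 42])
    def test_matches_independent_lp_encoding(self, seed):
        model, _, _ = generate_toy_model(SyntheticSpec(seed=seed))
        sol = solve_fba(model)
        assert sol.objective_value == pytest.approx(
            fba_oracle(model, "BIOMASS"), rel=1e-7
        )

    def test_matches_cobra_glpk(self, default_instance):
        """Cross-check against an entirely separate solver stack."""
        from remiflux.io import to_cobra

        model, _, _ = default_instance
        cmodel = to_cobra(model)
        cobra_opt = cmodel.optimize().objective_value
        assert solve_fba(model).objective_value == pytest.approx(cobra_opt, rel=1e-6)

    def test_unknown_objective_raises(self, chain_model):
        with pytest.raises(KeyError):
            solve_fba(chain_model, "NOPE")

    def test_infeasible_model_reported(self, chain_model):
        model = chain_model.copy()
        model.reactions["BIOMASS"].lower_bound = 50.0  # demands more than uptake allows
        sol = solve_fba(model)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}


def _ab_thermo_model(dgr0: float):
    """Reversible A<->B with a direct standard reaction energy."""
    model = MetabolicModel(
        "thermo_toy",
        [
            Metabolite("a_e", "e"),
            Metabolite("a_c", "c"),
            Metabolite("b_c", "c"),
            Metabolite("b_e", "e"),
        ],
        [
            Reaction("EX_a", {"a_e": -1.0}, kind="exchange"),
            Reaction("T_a", {"a_e": -1.0, "a_c": 1.0}, kind="transport"),
            Reaction("AB", {"a_c": -1.0, "b_c": 1.0}),
            Reaction("T_b", {"b_c": -1.0, "b_e": 1.0}, kind="transport"),
            Reaction("EX_b", {"b_e": -1.0}, kind="exchange"),
        ],
        {"c": "cytosol", "e": "extracellular"},
    )
    thermo = ThermoAnnotation(dGr_std={"AB": dgr0})
    return model, thermo


class TestTFA:
    def test_positive_dg_blocks_forward_flux(self):
        """+50 kJ/mol cannot be overcome by any concentration ratio within
        the default 1e-7..1e-1 bounds (RT ln spans ~ +-34.8 kJ/mol)."""
        model, thermo = _ab_thermo_model(+50.0)
        sol = solve_tfa(model, thermo, objective_reaction="AB")
        assert sol.ok
        assert sol.objective_value == pytest.approx(0.0, abs=1e-6)
        # backward flux remains possible
        sol_b = solve_tfa(model, thermo, objective_reaction="EX_a")
        assert sol_b.objective_value > 1.0

    def test_surmountable_dg_allows_flux(self):
        """+20 kJ/mol is inside what the concentration span can pay for."""
        model, thermo = _ab_thermo_model(+20.0)
        sol = solve_tfa(model, thermo, objective_reaction="AB")
        assert sol.objective_value > 1.0

    def test_empty_annotation_reduces_to_fba(self, default_instance):
        model, _, _ = default_instance
        fba = solve_fba(model)
        tfa = solve_tfa(model, ThermoAnnotation())
        assert tfa.objective_value == pytest.approx(fba.objective_value)

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_never_exceeds_fba(self, seed):
        model, thermo, _ = generate_toy_model(SyntheticSpec(seed=seed))
        fba = solve_fba(model).objective_value
        tfa = solve_tfa(model, thermo).objective_value
        assert tfa <= fba + 1e-7

    def test_matches_direction_enumeration_oracle(self):
        """Optimum equals exhaustive enumeration over direction patterns on
        a small planted-energy network."""
        model, thermo, _ = generate_toy_model(
            SyntheticSpec(n_metabolites=12, n_reactions=14,
                          n_consistent_gene_signals=2,
                          n_inconsistent_gene_signals=0,
                          n_metabolite_signals=1, n_exchanges=2)
        )
        # keep the covered set small enough for 3^k enumeration
        covered = sorted(thermo.covered_reactions(model))
        for rid in covered[5:]:
            thermo.dGr_std.pop(rid, None)
        thermo.dGf_std.clear()
        assert len(thermo.covered_reactions(model)) <= 5
        ours = solve_tfa(model, thermo).objective_value
        oracle = tfa_direction_enumeration(model, thermo, "BIOMASS")
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_direction_coupling_invariant(self, default_instance):
        """Forward flux through a covered reaction implies a favorable
        (non-positive) reaction energy in the returned solution."""
        model, thermo, _ = default_instance
        sol = solve_tfa(model, thermo)
        covered = thermo.covered_reactions(model)
        for rid in covered:
            if sol.fluxes[rid] > 1e-6:
                assert sol.extras[f"dG[{rid}]"] <= 1e-6

    def test_gibbs_energy_consistent_with_concentrations(self):
        model, thermo = _ab_thermo_model(-10.0)
        sol = solve_tfa(model, thermo, objective_reaction="AB")
        dg = sol.extras["dG[AB]"]
        expected = -10.0 + thermo.rt * (sol.extras["lnc[b_c]"] - sol.extras["lnc[a_c]"])
        assert dg == pytest.approx(expected, abs=1e-6)


class TestFVA:
    def test_dead_end_reaction_pinned_to_zero(self, blocked_instance):
        model, _, truth = blocked_instance
        ranges = flux_variability(model, reactions=sorted(truth.blocked_reactions))
        for rid in truth.blocked_reactions:
            assert ranges[rid] == pytest.approx((0.0, 0.0), abs=1e-7)

    def test_sole_carbon_exchange_pinned_at_full_objective(self, chain_model):
        ranges = flux_variability(
            chain_model, reactions=["EX_a"], objective_fraction=1.0
        )
        lo, hi = ranges["EX_a"]
        assert lo == pytest.approx(-10.0, abs=1e-6)
        assert hi == pytest.approx(-10.0, abs=1e-6)

    def test_matches_per_reaction_lp_oracle(self, default_instance):
        model, _, _ = default_instance
        ranges = flux_variability(model, objective_fraction=0.0)
        for rid, (lo, hi) in ranges.items():
            olo, ohi = fva_oracle(model, rid)
            assert lo == pytest.approx(olo, abs=1e-6)
            assert hi == pytest.approx(ohi, abs=1e-6)

    def test_envelops_optimal_fluxes(self, default_instance):
        model, _, _ = default_instance
        sol = solve_fba(model)
        ranges = flux_variability(model, objective_fraction=1.0)
        for rid, (lo, hi) in ranges.items():
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6

    def test_infeasible_base_fails_before_subproblems(self, chain_model):
        model = chain_model.copy()
        model.reactions["BIOMASS"].lower_bound = 50.0
        with pytest.raises(RuntimeError, match="base model"):
            flux_variability(model, objective_fraction=0.9)


class TestUptakeEstimation:
    def test_unit_yield_chain(self, chain_model):
        uptake = estimate_uptake_for_growth(chain_model, None, "EX_a", 10.0)
        assert uptake == pytest.approx(10.0)

    def test_half_yield_chain(self, chain_half_yield):
        uptake = estimate_uptake_for_growth(chain_half_yield, None, "EX_a", 5.0)
        assert uptake == pytest.approx(10.0)

    def test_unreachable_target_returns_none(self, chain_model):
        assert estimate_uptake_for_growth(chain_model, None, "EX_a", 99.0) is None

    def test_non_exchange_target_rejected(self, chain_model):
        with pytest.raises(KeyError):
            estimate_uptake_for_growth(chain_model, None, "AB", 1.0)


def test_thermo_tsv_roundtrip(tmp_path):
    thermo = ThermoAnnotation(
        dGf_std={"a_c": -3.5}, dGr_std={"R1": -12.0}, conc_lb={"a_c": 1e-6},
        conc_ub={"a_c": 1e-2},
    )
    path = tmp_path / "thermo.tsv"
    write_thermo_tsv(thermo, path)
    back = load_thermo_tsv(path)
    assert back.dGf_std == thermo.dGf_std
    assert back.dGr_std == thermo.dGr_std
    assert back.conc_lb == thermo.conc_lb
    assert back.conc_ub == thermo.conc_ub


def test_bad_concentration_bounds_rejected():
    with pytest.raises(ValueError):
        ThermoAnnotation(conc_lb={"a": 1e-2}, conc_ub={"a": 1e-6})


def test_coverage_fractions(default_instance):
    model, thermo, _ = default_instance
    cov = thermo.coverage(model)
    assert 0.7 <= cov["metabolite_coverage"] <= 0.9
    assert 0.8 <= cov["reaction_coverage"] <= 0.95
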