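"""Decomposition, blocked detection and gap-filling against brute force."""

import pytest

from remiflux.gapfill import (
    GapfillSolution,
    GapfillTask,
    apply_gapfill,
    decompose_network,
    find_blocked_reactions,
    gapfill,
    prioritize_blocked,
)
from remiflux.model import MetabolicModel, Metabolite, Reaction, parse_gpr
from remiflux.omics import OmicsData
from remiflux.synthetic import (
    SyntheticSpec,
    fixture_fig3_omics,
    fixture_fig3_pathways,
    generate_toy_model,
)

from oracles import blocked_oracle, gapfill_brute_force


def _two_chains_model(bridge_metabolite=None):
    """Two disjoint linear chains, optionally joined by one shared metabolite."""
    mets = [Metabolite(m, "c") for m in ("a1", "a2", "b1", "b2")]
    rxns = [
        Reaction("EX_a1", {"a1": -1.0}, kind="exchange"),
        Reaction("RA", {"a1": -1.0, "a2": 1.0}),
        Reaction("EX_a2", {"a2": -1.0}, kind="exchange"),
        Reaction("EX_b1", {"b1": -1.0}, kind="exchange"),
        Reaction("RB", {"b1": -1.0, "b2": 1.0}),
        Reaction("EX_b2", {"b2": -1.0}, kind="exchange"),
    ]
    if bridge_metabolite:
        mets.append(Metabolite(bridge_metabolite, "c"))
        for rxn in rxns:
            if rxn.id in ("RA", "RB"):
                rxn.stoichiometry[bridge_metabolite] = (
                    1.0 if rxn.id == "RA" else -1.0
                )
    model = MetabolicModel("chains", mets, rxns, {"c": "c"})
    model.validate(require_biomass=False)
    return model


class TestDecompose:
    def test_two_disjoint_chains(self):
        comps = decompose_network(_two_chains_model())
        assert len(comps) == 2
        assert comps[0].is_main and not comps[1].is_main

    def test_currency_bridge_ignored_when_listed(self):
        model = _two_chains_model(bridge_metabolite="atp")
        assert len(decompose_network(model)) == 2  # atp is currency by default
        assert len(decompose_network(model, currency_metabolites=["nad"])) == 1

    @pytest.mark.parametrize("seed", [1, 4, 9])
    def test_partition_property(self, seed):
        model, _, _ = generate_toy_model(
            SyntheticSpec(seed=seed, n_metabolites=23, n_reactions=33, n_blocked=3)
        )
        comps = decompose_network(model)
        all_rxns = [rid for c in comps for rid in c.reaction_ids]
        assert sorted(all_rxns) == sorted(model.reactions)
        assert sum(c.is_main for c in comps) == 1
        assert comps[0].size == max(c.size for c in comps)


class TestBlockedDetection:
    def test_fully_connected_chain_has_none(self, chain_model):
        assert find_blocked_reactions(chain_model) == set()

    def test_planted_dead_ends_found_exactly(self, blocked_instance):
        model, _, truth = blocked_instance
        assert find_blocked_reactions(model) == truth.blocked_reactions

    def test_matches_per_reaction_lp_oracle(self, blocked_instance):
        model, _, _ = blocked_instance
        assert find_blocked_reactions(model) == blocked_oracle(model)

    def test_invariant_under_bound_scaling(self, blocked_instance):
        model, _, _ = blocked_instance
        scaled = model.copy()
        for rxn in scaled.reactions.values():
            rxn.lower_bound *= 3.0
            rxn.upper_bound *= 3.0
        assert find_blocked_reactions(scaled) == find_blocked_reactions(model)

    def test_toluene_route_blocked_without_coa_transferase(self):
        tol, _, _ = fixture_fig3_pathways()
        assert find_blocked_reactions(tol) == {"S1", "S2", "S4", "S5"}

    def test_phe_route_blocked_and_intermediate_absent(self):
        _, phe, _ = fixture_fig3_pathways()
        assert "hpa_c" not in phe.metabolites
        blocked = find_blocked_reactions(phe)
        assert {"E1", "E2", "E3", "E4", "E5"} <= blocked
        assert "XOAA" not in blocked  # the working carbon route still runs


class TestPrioritize:
    def test_toluene_route_scores_three_de_genes(self):
        tol, _, _ = fixture_fig3_pathways()
        omics, _ = fixture_fig3_omics()
        tasks = prioritize_blocked(tol, find_blocked_reactions(tol), omics)
        assert len(tasks) == 1
        assert tasks[0].gene_hits == 3
        assert set(tasks[0].omics_evidence) >= {"gr1", "gr2", "gr2b"}

    def test_phe_route_scores_four_measured_metabolites(self):
        _, phe, _ = fixture_fig3_pathways()
        _, omics = fixture_fig3_omics()
        tasks = prioritize_blocked(phe, find_blocked_reactions(phe), omics)
        assert len(tasks) == 1
        assert tasks[0].metabolite_hits == 4

    def test_unsupported_blocked_reaction_excluded(self, blocked_instance):
        model, _, truth = blocked_instance
        tasks = prioritize_blocked(model, truth.blocked_reactions, OmicsData())
        assert tasks == []


class TestGapfill:
    def test_toluene_minimal_set_is_the_coa_transferase(self):
        tol, _, db = fixture_fig3_pathways()
        sol = gapfill(tol, db, GapfillTask(target="S1", target_type="reaction"))
        assert sol.feasible
        assert sol.size == 1
        assert sol.added_reaction_ids == ["GF_2836"]
        assert "scoA" in sol.genes_suggested

    def test_phe_minimal_set_has_three_steps(self):
        _, phe, db = fixture_fig3_pathways()
        sol = gapfill(phe, db, GapfillTask(target="E3", target_type="reaction"))
        assert sol.feasible
        assert sol.size == 3
        assert sol.added_reaction_ids == ["GF_11413", "GF_1141454", "GF_41128"]

    def test_metabolite_target_production(self):
        _, phe, db = fixture_fig3_pathways()
        sol = gapfill(phe, db, GapfillTask(target="hgt_c", target_type="metabolite"))
        assert sol.feasible and sol.size == 3

    @pytest.mark.parametrize("target", ["S1", "E3"])
    def test_minimality_certified_by_brute_force(self, target):
        tol, phe, db = fixture_fig3_pathways()
        model = tol if target == "S1" else phe
        sol = gapfill(model, db, GapfillTask(target=target, target_type="reaction"))
        size, sets = gapfill_brute_force(model, db, target)
        assert sol.size == size
        assert sorted(sol.added_reaction_ids) in sets

    def test_decoys_never_selected(self):
        tol, phe, db = fixture_fig3_pathways()
        for model, target in ((tol, "S1"), (phe, "E3")):
            sol = gapfill(model, db, GapfillTask(target=target, target_type="reaction"))
            assert not any("decoy" in rid for rid in sol.added_reaction_ids)
            _, sets = gapfill_brute_force(model, db, target)
            for alt in sets:
                assert not any("decoy" in rid for rid in alt)

    def test_unfillable_target_reported(self):
        tol, _, db = fixture_fig3_pathways()
        hopeless = db.copy()
        del hopeless.reactions["GF_2836"]
        sol = gapfill(tol, hopeless, GapfillTask(target="S1", target_type="reaction"))
        assert not sol.feasible
        assert sol.added_reaction_ids == []

    def test_alternative_sets_all_minimal_and_distinct(self):
        """With two equivalent repair copies both singletons are enumerated."""
        tol, _, db = fixture_fig3_pathways()
        db2 = db.copy()
        twin = db2.reactions["GF_2836"]
        import copy

        other = copy.deepcopy(twin)
        other.id = "GF_2836_b"
        db2.reactions[other.id] = other
        sol = gapfill(tol, db2, GapfillTask(target="S1", target_type="reaction"))
        assert sol.size == 1
        assert sorted(map(tuple, sol.alternative_sets)) == [
            ("GF_2836",), ("GF_2836_b",)
        ]


class TestApplyGapfill:
    def test_empty_solution_is_identity(self, chain_model):
        out = apply_gapfill(chain_model, GapfillSolution(feasible=False))
        assert out == chain_model

    def test_toluene_route_carries_flux_after_fill(self):
        tol, _, db = fixture_fig3_pathways()
        sol = gapfill(tol, db, GapfillTask(target="S1", target_type="reaction"))
        filled = apply_gapfill(tol, sol)
        assert find_blocked_reactions(filled) == set()

    def test_planted_gap_fill_shrinks_blocked_set_exactly(self, blocked_instance):
        model, _, truth = blocked_instance
        target = sorted(truth.blocked_reactions)[0]
        sol = gapfill(model, truth.universal_db,
                      GapfillTask(target=target, target_type="reaction"))
        assert sorted(sol.added_reaction_ids) == truth.gapfill_sets[target]
        filled = apply_gapfill(model, sol)
        assert find_blocked_reactions(filled) == set()

    def test_never_increases_blocked_count(self, blocked_instance):
        model, _, truth = blocked_instance
        before = len(find_blocked_reactions(model))
        target = sorted(truth.blocked_reactions)[0]
        sol = gapfill(model, truth.universal_db,
                      GapfillTask(target=target, target_type="reaction"))
        after = len(find_blocked_reactions(apply_gapfill(model, sol)))
        assert after <= before

    def test_id_collision_renamed(self, blocked_instance, caplog):
        model, _, truth = blocked_instance
        target = sorted(truth.blocked_reactions)[0]
        sol = gapfill(model, truth.universal_db,
                      GapfillTask(target=target, target_type="reaction"))
        clashed = model.copy()
        import copy

        ghost = copy.deepcopy(sol.added_reactions[0])
        clashed.reactions[ghost.id] = ghost
        with caplog.at_level("WARNING"):
            out = apply_gapfill(clashed, sol)
        assert f"{ghost.id}_gf" in out.reactions
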