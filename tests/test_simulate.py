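import dataclasses

import numpy as np
import pytest

from metscreen.network import (
    Component,
    KineticLaw,
    MetabolicModel,
    Pathway,
    Reaction,
    ReactionParticipant,
)
from metscreen.reference import dataflow_reference
from metscreen.simulate import (
    DivergenceError,
    SimulationConfig,
    evaluate_reaction,
    initialize_state,
    propagate,
    simulate_cohort,
)
from metscreen.synth import generate_cohort, generate_network

from conftest import random_dag_spec


class TestInitializeState:
    def test_genes_seeded_everything_else_zero(self, toy_model):
        state = initialize_state(toy_model, {"HK1": 2.0})
        assert state.values["HK1"] == 2.0
        assert state.values["ADA"] == 0.0  # gene absent from profile
        assert all(state.values[c.id] == 0.0 for c in toy_model.components if c.kind != "gene")

    def test_multiple_symbols_collapse_by_mean(self, toy_model):
        gene_map = {"probe1": "HK1", "probe2": "HK1"}
        state = initialize_state(toy_model, {"probe1": 1.0, "probe2": 3.0}, gene_map=gene_map)
        assert state.values["HK1"] == 2.0

    def test_empty_profile_gives_all_zero_state(self, toy_model):
        state = initialize_state(toy_model, {})
        assert set(state.values.values()) == {0.0}

    def test_negative_expression_rejected(self, toy_model):
        with pytest.raises(ValueError, match="finite and >= 0"):
            initialize_state(toy_model, {"HK1": -1.0})

    def test_unknown_gene_map_target_rejected(self, toy_model):
        with pytest.raises(ValueError, match="unknown components"):
            initialize_state(toy_model, {"x": 1.0}, gene_map={"x": "nope"})

    def test_log2_flag_exponentiates(self, toy_model):
        cfg = SimulationConfig(expression_is_log2=True)
        state = initialize_state(toy_model, {"HK1": 3.0}, config=cfg)
        assert state.values["HK1"] == 8.0


class TestEvaluateReaction:
    def test_mass_action_product_of_reactants(self):
        r = Reaction(
            "r",
            (ReactionParticipant("A"), ReactionParticipant("B")),
            (ReactionParticipant("C"),),
            KineticLaw("mass_action", 1.0),
            {"pw"},
        )
        assert evaluate_reaction(r, {"A": 2.0, "B": 3.0, "C": 0.0}) == {"C": 6.0}

    def test_zero_reactant_annihilates(self):
        r = Reaction(
            "r",
            (ReactionParticipant("A"), ReactionParticipant("B")),
            (ReactionParticipant("C"),),
            KineticLaw("mass_action", 7.0),
            {"pw"},
        )
        assert evaluate_reaction(r, {"A": 0.0, "B": 123.0, "C": 1.0}) == {"C": 0.0}

    def test_role_acts_as_exponent_and_k_scales(self):
        r = Reaction(
            "r",
            (ReactionParticipant("A", role=2.0),),
            (ReactionParticipant("C", role=1.0),),
            KineticLaw("mass_action", 0.5),
            {"pw"},
        )
        assert evaluate_reaction(r, {"A": 2.0, "C": 0.0}) == {"C": 0.5 * 2.0**2}

    def test_product_role_scales_contribution(self):
        r = Reaction(
            "r",
            (ReactionParticipant("A"),),
            (ReactionParticipant("C", role=3.0),),
            KineticLaw("unit"),
            {"pw"},
        )
        assert evaluate_reaction(r, {"A": 2.0, "C": 0.0}) == {"C": 6.0}


class TestPropagate:
    def test_chain_matches_recursive_substitution(self, chain_model):
        cfg = SimulationConfig(damping=1.0)
        state0 = initialize_state(chain_model, {"G": 2.0}, config=cfg)
        state, rec = propagate(chain_model, state0, cfg)
        assert rec.converged
        assert state.values["P1"] == 2.0
        assert state.values["P2"] == 2.0

    def test_all_zero_genes_give_zero_fixed_point(self, toy_model):
        state0 = initialize_state(toy_model, {})
        state, rec = propagate(toy_model, state0)
        assert rec.converged
        assert set(state.values.values()) == {0.0}

    def test_cycle_converges_to_analytic_fixed_point(self, cycle_model):
        g = 3.0
        state0 = initialize_state(cycle_model, {"G": g})
        state, rec = propagate(cycle_model, state0, SimulationConfig(tolerance=1e-12))
        assert rec.converged
        # P1 = g + 0.25 P1 and P2 = P1 / 2 (geometric series limit)
        assert state.values["P1"] == pytest.approx(g / 0.75, abs=1e-9)
        assert state.values["P2"] == pytest.approx(g / 1.5, abs=1e-9)

    def test_final_delta_below_tolerance_when_converged(self, cycle_model):
        state0 = initialize_state(cycle_model, {"G": 1.0})
        cfg = SimulationConfig(tolerance=1e-9)
        _, rec = propagate(cycle_model, state0, cfg)
        assert rec.converged and rec.final_delta < cfg.tolerance

    def test_single_pass_supported(self, chain_model):
        cfg = SimulationConfig(damping=1.0, max_iterations=1)
        state0 = initialize_state(chain_model, {"G": 2.0}, config=cfg)
        state, rec = propagate(chain_model, state0, cfg)
        assert rec.iterations == 1
        assert state.values["P1"] == 2.0  # one hop reached, second not yet
        assert state.values["P2"] == 0.0

    def test_gene_products_stay_clamped(self):
        # a reaction that tries to overwrite a gene; genes are sources
        pw = "pw"
        model = MetabolicModel(
            (
                Component("G", kind="gene", pathways={pw}),
                Component("P", pathways={pw}),
            ),
            (
                Reaction("r1", (ReactionParticipant("G"),), (ReactionParticipant("P"),), KineticLaw(), {pw}),
                Reaction("r2", (ReactionParticipant("P"),), (ReactionParticipant("G"),), KineticLaw(), {pw}),
            ),
            (Pathway(pw),),
        )
        state0 = initialize_state(model, {"G": 5.0})
        state, rec = propagate(model, state0, SimulationConfig(damping=1.0))
        assert rec.converged
        assert state.values["G"] == 5.0

    def test_divergent_growth_raises_with_iteration(self):
        pw = "pw"
        model = MetabolicModel(
            (
                Component("G", kind="gene", pathways={pw}),
                Component("P", pathways={pw}),
            ),
            (
                Reaction("feed", (ReactionParticipant("G"),), (ReactionParticipant("P"),), KineticLaw(), {pw}),
                # self-amplifying loop with gain 4
                Reaction("loop", (ReactionParticipant("P", role=2.0),), (ReactionParticipant("P"),),
                         KineticLaw("mass_action", 4.0), {pw}),
            ),
            (Pathway(pw),),
        )
        state0 = initialize_state(model, {"G": 10.0})
        with pytest.raises(DivergenceError, match="iteration"):
            propagate(model, state0, SimulationConfig(damping=1.0))

    @pytest.mark.parametrize("seed", range(12))
    def test_acyclic_propagation_matches_reference_oracle(self, seed):
        spec = random_dag_spec(seed)
        model = generate_network(spec)
        profile = generate_cohort(model, spec)[0]
        cfg = SimulationConfig(damping=1.0)
        state0 = initialize_state(model, profile, config=cfg)
        state, rec = propagate(model, state0, cfg)
        assert rec.converged
        ref = dataflow_reference(model, {c.id: state0.values[c.id] for c in model.genes()})
        err = max(abs(state.values[k] - ref[k]) for k in ref)
        assert err < 1e-12 * max(1.0, max(abs(v) for v in ref.values()))

    def test_scaling_property_on_unit_role_chain(self, chain_model):
        cfg = SimulationConfig(damping=1.0)
        s1, _ = propagate(chain_model, initialize_state(chain_model, {"G": 2.0}, config=cfg), cfg)
        s3, _ = propagate(chain_model, initialize_state(chain_model, {"G": 6.0}, config=cfg), cfg)
        for cid in ("P1", "P2"):
            assert s3.values[cid] == pytest.approx(3.0 * s1.values[cid], rel=1e-12)


class TestSimulateCohort:
    def test_matrix_shape_and_column_order(self, toy_model):
        profiles = [
            {"HK1": 1.0, "ADA": 2.0},
            {"HK1": 3.0},
        ]
        from metscreen.profiles import ExpressionProfile

        profs = [ExpressionProfile(f"cl{i}", p) for i, p in enumerate(profiles)]
        matrix, records = simulate_cohort(toy_model, profs)
        assert matrix.shape == (6, 2)
        assert list(matrix.columns) == ["cl0", "cl1"]
        assert all(r.converged for r in records)

    def test_duplicate_profiles_give_identical_columns(self, toy_model):
        from metscreen.profiles import ExpressionProfile

        profs = [
            ExpressionProfile("a", {"HK1": 1.5, "ADA": 0.5}),
            ExpressionProfile("b", {"HK1": 1.5, "ADA": 0.5}),
        ]
        matrix, _ = simulate_cohort(toy_model, profs)
        assert (matrix["a"] == matrix["b"]).all()

    def test_determinism_bit_identical(self, planted_dataset):
        model = planted_dataset["model"]
        profiles = planted_dataset["profiles"][:10]
        m1, _ = simulate_cohort(model, profiles)
        m2, _ = simulate_cohort(model, profiles)
        assert (m1.to_numpy() == m2.to_numpy()).all()
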