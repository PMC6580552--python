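import numpy as np
import pytest

from metscreen.network import (
    Component,
    KineticLaw,
    MetabolicModel,
    Pathway,
    Reaction,
    ReactionParticipant,
)
from metscreen.profiles import join_cohort
from metscreen.simulate import simulate_cohort
from metscreen.synth import (
    SyntheticSpec,
    annotations_from_cohort,
    generate_cohort,
    generate_network,
    generate_responses,
    make_planted_spec,
)


def _p(cid, role=1.0):
    return ReactionParticipant(cid, role)


@pytest.fixture
def toy_model():
    """Six components, three reactions, two pathways: two genes feeding a
    small glycolysis-flavoured chain."""
    pw1, pw2 = "glycolysis", "purine"
    components = (
        Component("HK1", kind="gene", pathways={pw1}),
        Component("ADA", kind="gene", pathways={pw2}),
        Component("hexokinase", kind="protein", pathways={pw1}),
        Component("g6p", kind="compound", pathways={pw1, pw2}),
        Component("inosine", kind="compound", pathways={pw2}),
        Component("urate", kind="compound", pathways={pw2}),
    )
    reactions = (
        Reaction("r_translate", (_p("HK1"),), (_p("hexokinase"),), KineticLaw("unit"), {pw1}),
        Reaction("r_phos", (_p("hexokinase"),), (_p("g6p"),), KineticLaw("mass_action", 1.0), {pw1}),
        Reaction("r_deam", (_p("ADA"), _p("inosine")), (_p("urate"),), KineticLaw("mass_action", 0.5), {pw2}),
    )
    pathways = (Pathway(pw1, "Glycolysis", "metabolic"), Pathway(pw2, "Purine", "metabolic"))
    return MetabolicModel(components, reactions, pathways)


@pytest.fixture
def chain_model():
    """Acyclic chain: gene G -> P1 -> P2 with unit rate constants."""
    pw = "pw"
    return MetabolicModel(
        (
            Component("G", kind="gene", pathways={pw}),
            Component("P1", pathways={pw}),
            Component("P2", pathways={pw}),
        ),
        (
            Reaction("r1", (_p("G"),), (_p("P1"),), KineticLaw("mass_action", 1.0), {pw}),
            Reaction("r2", (_p("P1"),), (_p("P2"),), KineticLaw("mass_action", 1.0), {pw}),
        ),
        (Pathway(pw),),
    )


@pytest.fixture
def cycle_model():
    """Gene feed into a two-reaction cycle P1 <-> P2 with k = 0.5 each.

    Fixed point: P1 = g + 0.25 P1 => P1 = g / 0.75, P2 = P1 / 2.
    """
    pw = "pw"
    return MetabolicModel(
        (
            Component("G", kind="gene", pathways={pw}),
            Component("P1", pathways={pw}),
            Component("P2", pathways={pw}),
        ),
        (
            Reaction("feed", (_p("G"),), (_p("P1"),), KineticLaw("mass_action", 1.0), {pw}),
            Reaction("fwd", (_p("P1"),), (_p("P2"),), KineticLaw("mass_action", 0.5), {pw}),
            Reaction("back", (_p("P2"),), (_p("P1"),), KineticLaw("mass_action", 0.5), {pw}),
        ),
        (Pathway(pw),),
    )


@pytest.fixture(scope="session")
def planted_dataset():
    """One small end-to-end synthetic dataset with a planted common signature."""
    spec = SyntheticSpec(seed=7, n_cell_lines=120)
    model = generate_network(spec)
    profiles = generate_cohort(model, spec)
    sim_matrix, conv = simulate_cohort(model, profiles)
    spec = make_planted_spec(spec, model, sim_matrix, n_planted=5, effect_size=1.5)
    responses, truth = generate_responses(model, profiles, sim_matrix, spec)
    cohort = join_cohort(profiles, responses, annotations_from_cohort(profiles))
    return {
        "spec": spec,
        "model": model,
        "profiles": profiles,
        "sim_matrix": sim_matrix,
        "convergence": conv,
        "responses": responses,
        "truth": truth,
        "cohort": cohort,
    }


def random_dag_spec(seed: int) -> SyntheticSpec:
    """A feasible small acyclic network spec (<= 30 reactions)."""
    rng = np.random.default_rng(seed)
    n_comp = int(rng.integers(8, 22))
    n_gene = max(1, round(0.2 * n_comp))
    n_rxn = int(rng.integers(n_comp - n_gene, 31))
    return SyntheticSpec(
        n_components=n_comp,
        n_reactions=n_rxn,
        n_pathways=3,
        n_cell_lines=1,
        seed=seed,
        back_edge_fraction=0.0,
    )
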