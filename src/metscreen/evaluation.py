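"""End-to-end evaluation routines: oracle cross-checks and benchmark runs.

These functions recompute, from scratch, the quantities that characterize the
pipeline's correctness and statistical behaviour: agreement of the iterative
engine with an independent recursive evaluator on acyclic networks, the
analytic fixed point of a feedback cycle, exact agreement of the Spearman
implementation with the textbook rank-difference formula, recovery of planted
drug-sensitivity signatures, and false-positive control on null data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .network import (
    Component,
    KineticLaw,
    MetabolicModel,
    Pathway,
    Reaction,
    ReactionParticipant,
)
from .profiles import join_cohort
from .reference import dataflow_reference
from .screen import CorrelationRecord, extract_signature, screen_components, spearman_correlation, summarize_drug
from .simulate import SimulationConfig, initialize_state, propagate, simulate_cohort
from .synth import (
    SyntheticSpec,
    annotations_from_cohort,
    generate_cohort,
    generate_network,
    generate_responses,
    make_planted_spec,
)


def random_acyclic_spec(seed: int, max_reactions: int = 30) -> SyntheticSpec:
    """A feasible random acyclic network spec with at most ``max_reactions``."""
    rng = np.random.default_rng(seed)
    n_comp = int(rng.integers(8, 22))
    n_gene = max(1, round(0.2 * n_comp))
    n_rxn = int(rng.integers(n_comp - n_gene, max_reactions + 1))
    return SyntheticSpec(
        n_components=n_comp,
        n_reactions=n_rxn,
        n_pathways=3,
        n_cell_lines=1,
        seed=seed,
        back_edge_fraction=0.0,
    )


def simulator_oracle_max_error(n_networks: int = 100, seed0: int = 0) -> float:
    """Max-abs deviation of undamped propagation from recursive substitution
    over random acyclic networks."""
    worst = 0.0
    cfg = SimulationConfig(damping=1.0)
    for seed in range(seed0, seed0 + n_networks):
        spec = random_acyclic_spec(seed)
        model = generate_network(spec)
        profile = generate_cohort(model, spec)[0]
        state0 = initialize_state(model, profile, config=cfg)
        state, record = propagate(model, state0, cfg)
        if not record.converged:
            return float("inf")
        ref = dataflow_reference(model, {c.id: state0.values[c.id] for c in model.genes()})
        worst = max(worst, max(abs(state.values[k] - ref[k]) for k in ref))
    return worst


def cycle_fixture_model(feed_k: float = 1.0, loop_k: float = 0.5) -> MetabolicModel:
    """Gene-fed two-reaction cycle; fixed point P1 = g/(1 - loop_k**2), P2 = loop_k*P1."""
    pw = "pw"
    p = ReactionParticipant
    return MetabolicModel(
        (
            Component("G", kind="gene", pathways={pw}),
            Component("P1", pathways={pw}),
            Component("P2", pathways={pw}),
        ),
        (
            Reaction("feed", (p("G"),), (p("P1"),), KineticLaw("mass_action", feed_k), {pw}),
            Reaction("fwd", (p("P1"),), (p("P2"),), KineticLaw("mass_action", loop_k), {pw}),
            Reaction("back", (p("P2"),), (p("P1"),), KineticLaw("mass_action", loop_k), {pw}),
        ),
        (Pathway(pw),),
    )


def cycle_fixture_error(gene_value: float = 3.0, loop_k: float = 0.5) -> float:
    """Abs deviation of the converged cycle state from its analytic fixed point."""
    model = cycle_fixture_model(loop_k=loop_k)
    state0 = initialize_state(model, {"G": gene_value})
    state, record = propagate(model, state0, SimulationConfig(tolerance=1e-12))
    if not record.converged:
        return float("inf")
    p1 = gene_value / (1.0 - loop_k**2)
    p2 = loop_k * p1
    return max(abs(state.values["P1"] - p1), abs(state.values["P2"] - p2))


def rank_formula_rho(x: tuple[int, ...], y: tuple[int, ...]) -> float:
    """Textbook Spearman formula for untied data: 1 - 6*sum(d^2)/(n(n^2-1))."""
    n = len(x)
    rx = {v: i + 1 for i, v in enumerate(sorted(x))}
    ry = {v: i + 1 for i, v in enumerate(sorted(y))}
    d2 = sum((rx[a] - ry[b]) ** 2 for a, b in zip(x, y))
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def spearman_permutation_check(n_samples: int = 10_000, seed: int = 0) -> float:
    """Max-abs deviation from the rank-difference formula over sampled
    permutation pairs with n <= 6."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    perms = {n: list(itertools.permutations(range(1, n + 1))) for n in range(3, 7)}
    for _ in range(n_samples):
        n = int(rng.integers(3, 7))
        px = perms[n][int(rng.integers(len(perms[n])))]
        py = perms[n][int(rng.integers(len(perms[n])))]
        got = spearman_correlation(px, py, min_n=2).rho
        worst = max(worst, abs(got - rank_formula_rho(px, py)))
    return worst


@dataclass
class RecoveryOutcome:
    per_drug_sensitivity: dict[str, float]  # mean over seeds
    full_recovery_runs: int
    n_seeds: int
    signature_sizes: list[int]


def _one_synthetic_screen(seed: int, n_cell_lines: int, planted: bool,
                          n_planted: int = 5, effect_size: float = 1.5,
                          noise_sd: float = 0.5):
    spec = SyntheticSpec(seed=seed, n_cell_lines=n_cell_lines, noise_sd=noise_sd)
    model = generate_network(spec)
    profiles = generate_cohort(model, spec)
    sim_matrix, _ = simulate_cohort(model, profiles)
    if planted:
        spec = make_planted_spec(spec, model, sim_matrix, n_planted, effect_size)
    responses, truth = generate_responses(model, profiles, sim_matrix, spec)
    cohort = join_cohort(profiles, responses, annotations_from_cohort(profiles))
    result = screen_components(sim_matrix, cohort)
    return model, cohort, result, truth


def planted_recovery(n_seeds: int = 10, seed0: int = 0, n_cell_lines: int = 200,
                     n_planted: int = 5, effect_size: float = 1.5,
                     noise_sd: float = 0.5) -> RecoveryOutcome:
    """Sensitivity of the end-to-end screen for planted common signatures."""
    sens: dict[str, list[float]] = {}
    full = 0
    sizes = []
    for seed in range(seed0, seed0 + n_seeds):
        model, cohort, result, truth = _one_synthetic_screen(
            seed, n_cell_lines, True, n_planted, effect_size, noise_sd
        )
        planted = truth.common_components()
        for d in cohort.drugs:
            found = planted & result.significant_components(d)
            sens.setdefault(d, []).append(len(found) / len(planted))
        signature = extract_signature(result, cohort.drugs, model=model)
        sizes.append(len(signature.members))
        if planted <= signature.component_ids():
            full += 1
    return RecoveryOutcome(
        {d: float(np.mean(v)) for d, v in sens.items()}, full, n_seeds, sizes
    )


def null_false_positives(n_seeds: int = 20, seed0: int = 0,
                         n_cell_lines: int = 200) -> float:
    """Mean number of significant (component, drug) records per run with no
    planted effects (Bonferroni false-positive control)."""
    total = 0
    for seed in range(seed0, seed0 + n_seeds):
        _, _, result, _ = _one_synthetic_screen(seed, n_cell_lines, planted=False)
        total += sum(r.significant for r in result.records)
    return total / n_seeds


def impact_score_fixture(n_significant: int = 1220, n_components: int = 3755) -> float:
    """Impact score of a drug with the given significant count in a model of
    the given size (fraction of all model components affected)."""
    pw = Pathway("pw")
    components = tuple(
        Component(f"c{i:04d}", pathways=frozenset({"pw"})) for i in range(n_components)
    )
    model = MetabolicModel(components, (), (pw,))
    records = [
        CorrelationRecord(c.id, "drug", 0.3, 1e-8, 1e-4, 400, i < n_significant)
        for i, c in enumerate(components)
    ]
    return summarize_drug(records, model).impact_score
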