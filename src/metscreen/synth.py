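"""Synthetic networks, expression cohorts and IC50 tables with known truth.

Stands in for a real cell-line panel: a pathway-annotated reaction network at
configurable dimensions, log-normal expression for a cohort of cell lines
spread over cancer types, and per-drug IC50 vectors built either as monotone
functions of selected simulated component values plus noise (planted
signature) or as pure noise (null data).  Every generator is deterministic
under the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import (
    Component,
    KineticLaw,
    MetabolicModel,
    Pathway,
    Reaction,
    ReactionParticipant,
)
from .profiles import DrugResponseTable, ExpressionProfile

#: the eight receptor tyrosine kinase inhibitors screened in the study data
DEFAULT_DRUGS = (
    "AEW541",
    "erlotinib",
    "lapatinib",
    "PF-2341066",
    "PHA-665752",
    "sorafenib",
    "TKI258",
    "ZD6474",
)

DEFAULT_CANCER_TYPES = ("breast", "lung", "liver", "pancreas", "cns", "colon")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults are the small test scale (300 components / 400 reactions /
    12 pathways / 120 cell lines); pass the full dimensions to emulate a
    genome-scale model and panel.
    """

    n_components: int = 300
    n_reactions: int = 400
    n_pathways: int = 12
    n_cell_lines: int = 120
    cancer_types: tuple[str, ...] = DEFAULT_CANCER_TYPES
    drugs: tuple[str, ...] = DEFAULT_DRUGS
    # planted: drug -> list of (component_id, effect_size, direction)
    planted: dict[str, list[tuple[str, float, int]]] | None = None
    noise_sd: float = 0.5
    seed: int = 0
    # network shape
    gene_fraction: float = 0.2
    back_edge_fraction: float = 0.05
    two_reactant_fraction: float = 0.3
    role2_fraction: float = 0.05
    # expression model (natural-log scale)
    gene_baseline_sd: float = 0.5
    type_shift_sd: float = 0.25
    expression_sd: float = 0.5

    def __post_init__(self):
        if self.n_components < 2 or self.n_reactions < 1 or self.n_pathways < 1:
            raise ValueError("need n_components >= 2, n_reactions >= 1, n_pathways >= 1")
        if self.n_cell_lines < 1 or not self.cancer_types or not self.drugs:
            raise ValueError("need cell lines, cancer types and drugs")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: per drug, component -> (effect_size, direction)."""

    per_drug: dict[str, dict[str, tuple[float, int]]] = field(default_factory=dict)

    def planted_components(self, drug: str) -> set[str]:
        return set(self.per_drug.get(drug, {}))

    def common_components(self) -> set[str]:
        sets = [set(v) for v in self.per_drug.values()]
        return set.intersection(*sets) if sets else set()

    def to_dict(self) -> dict:
        return {
            d: {c: {"effect_size": e, "direction": s} for c, (e, s) in comps.items()}
            for d, comps in self.per_drug.items()
        }


def generate_network(spec: SyntheticSpec) -> MetabolicModel:
    """Random pathway-annotated network, connected from its gene sources.

    Components are indexed so genes come first; every non-gene component gets
    at least one producing reaction drawing on lower-indexed components, which
    makes the whole network reachable from genes by induction, and extra
    reactions add further forward edges.  Cycles are introduced as dedicated
    two-component feedback pairs (u -> v -> u, rate constant 0.5 each, fed by
    one upstream component); every cycle in the network is such a pair, whose
    loop gain of 0.25 keeps the damped fixed-point iteration contractive.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_components
    n_genes = max(1, int(round(spec.gene_fraction * n)))
    n_cycles = int(round(spec.back_edge_fraction * spec.n_reactions / 2))
    # each cycle pair consumes 2 components and 3 reactions
    n_cycles = max(0, min(n_cycles, (n - n_genes - 1) // 2))
    n_main = n - 2 * n_cycles  # genes + feed-forward components
    n_required = (n_main - n_genes) + 3 * n_cycles
    if spec.n_reactions < n_required:
        raise ValueError(
            f"{spec.n_reactions} reactions cannot connect "
            f"{n - n_genes} non-gene components (need >= {n_required})"
        )

    pathways = tuple(
        Pathway(f"pw{i:02d}", f"pathway_{i:02d}", "signaling" if i % 5 == 4 else "metabolic")
        for i in range(spec.n_pathways)
    )
    other_kinds = ("protein", "compound", "compound", "other")
    components = []
    for i in range(n):
        kind = "gene" if i < n_genes else other_kinds[rng.integers(len(other_kinds))]
        n_pw = int(rng.integers(1, min(3, spec.n_pathways) + 1))
        pw = rng.choice(spec.n_pathways, size=n_pw, replace=False)
        components.append(
            Component(f"c{i:05d}", f"{kind}_{i:05d}", kind, frozenset(f"pw{j:02d}" for j in pw))
        )
    # guarantee non-empty pathways
    used = {p for c in components for p in c.pathways}
    for k, p in enumerate(pathways):
        if p.id not in used:
            c = components[k % n]
            components[k % n] = replace(c, pathways=c.pathways | {p.id})

    comp_pw = {c.id: c.pathways for c in components}

    def make_reaction(idx: int, product_i: int, reactant_pool_hi: int, back_edge: bool) -> Reaction:
        n_reac = 2 if (reactant_pool_hi > 1 and rng.random() < spec.two_reactant_fraction) else 1
        reac_i = rng.choice(reactant_pool_hi, size=n_reac, replace=False)
        reactants = tuple(
            ReactionParticipant(
                components[j].id, 2.0 if rng.random() < spec.role2_fraction else 1.0
            )
            for j in sorted(reac_i)
        )
        products = (ReactionParticipant(components[product_i].id, 1.0),)
        k = 0.1 if back_edge else float(rng.uniform(0.5, 1.5))
        pw = frozenset().union(*(comp_pw[q.component_id] for q in reactants + products))
        return Reaction(f"r{idx:05d}", reactants, products, KineticLaw("mass_action", k), pw)

    def pair_reaction(idx: int, src_i: int, dst_i: int, k: float) -> Reaction:
        reactants = (ReactionParticipant(components[src_i].id, 1.0),)
        products = (ReactionParticipant(components[dst_i].id, 1.0),)
        pw = comp_pw[components[src_i].id] | comp_pw[components[dst_i].id]
        return Reaction(f"r{idx:05d}", reactants, products, KineticLaw("mass_action", k), pw)

    reactions = []
    # one producing reaction per feed-forward non-gene component, reactants strictly earlier
    for i in range(n_genes, n_main):
        reactions.append(make_reaction(len(reactions), i, i, back_edge=False))
    # contractive feedback pairs appended after the feed-forward part
    for t in range(n_cycles):
        u, v = n_main + 2 * t, n_main + 2 * t + 1
        feed = int(rng.integers(0, n_main))
        reactions.append(pair_reaction(len(reactions), feed, u, float(rng.uniform(0.5, 1.5))))
        reactions.append(pair_reaction(len(reactions), u, v, 0.5))
        reactions.append(pair_reaction(len(reactions), v, u, 0.5))
    # extra forward reactions up to the requested count
    while len(reactions) < spec.n_reactions:
        i = int(rng.integers(n_genes, n_main))
        reactions.append(make_reaction(len(reactions), i, i, back_edge=False))
    return MetabolicModel(tuple(components), tuple(reactions), pathways)


def generate_cohort(model: MetabolicModel, spec: SyntheticSpec) -> list[ExpressionProfile]:
    """Log-normal expression with per-cancer-type mean shifts.

    value = exp(baseline_g + shift_{type,g} + eps), eps ~ N(0, expression_sd);
    cell lines are assigned round-robin to cancer types.
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = [c.id for c in model.genes()]
    baseline = rng.normal(0.0, spec.gene_baseline_sd, size=len(genes))
    shifts = {
        t: rng.normal(0.0, spec.type_shift_sd, size=len(genes)) for t in spec.cancer_types
    }
    profiles = []
    for j in range(spec.n_cell_lines):
        ctype = spec.cancer_types[j % len(spec.cancer_types)]
        eps = rng.normal(0.0, spec.expression_sd, size=len(genes)) if spec.expression_sd > 0 else 0.0
        logv = baseline + shifts[ctype] + eps
        values = dict(zip(genes, np.exp(logv).tolist()))
        profiles.append(ExpressionProfile(f"cl_{j:04d}", values, ctype))
    return profiles


def _choose_planted(
    model: MetabolicModel,
    sim_matrix: pd.DataFrame,
    n_planted: int,
    effect_size: float,
    rng: np.random.Generator,
    max_mutual_rho: float | None = None,
) -> list[tuple[str, float, int]]:
    """Sample planted components with bounded mutual rank correlation and
    directions chosen so the planted effects do not cancel.

    Network components share upstream drivers, so two random components can be
    near-duplicates; planting correlated components with opposing signs
    attenuates (or cancels) each one's marginal association with the response,
    leaving no recoverable ground truth.  Candidates are drawn in random order
    and accepted while their |Spearman rho| with every already-accepted
    component stays below ``max_mutual_rho`` (default max(0.15, 2/sqrt(n)),
    i.e. never below the sampling floor of a correlation between independent
    vectors); the +/-1 direction vector is then the one, over all
    2**n_planted assignments, that minimizes the worst signed
    cross-correlation working against any single component.
    """
    from scipy import stats

    gene_ids = {c.id for c in model.genes()}
    X = sim_matrix.to_numpy(dtype=float)
    if max_mutual_rho is None:
        max_mutual_rho = max(0.15, 2.0 / np.sqrt(X.shape[1]))
    std = X.std(axis=1)
    eligible = [
        i for i, (cid, s) in enumerate(zip(sim_matrix.index, std))
        if s > 1e-12 and cid not in gene_ids
    ]
    if len(eligible) < n_planted:
        raise ValueError(f"only {len(eligible)} non-constant components; cannot plant {n_planted}")
    order = rng.permutation(len(eligible))
    accepted: list[int] = []
    accepted_ranks: list[np.ndarray] = []
    for pos in order:
        i = eligible[int(pos)]
        r = stats.rankdata(X[i])
        rc = r - r.mean()
        norm = float(np.sqrt(rc @ rc))
        ok = all(abs(float(rc @ prev) / (norm * float(np.sqrt(prev @ prev)))) < max_mutual_rho
                 for prev in accepted_ranks)
        if ok:
            accepted.append(i)
            accepted_ranks.append(rc)
        if len(accepted) == n_planted:
            break
    if len(accepted) < n_planted:
        raise ValueError(
            f"could not find {n_planted} mutually decorrelated components (got {len(accepted)})"
        )

    # direction assignment: maximize the worst-case aligned signal
    R = np.array(accepted_ranks)
    C = np.corrcoef(R)
    k = len(accepted)
    best_dirs, best_penalty = None, np.inf
    for bits in range(2**k):
        d = np.array([1 if bits >> j & 1 else -1 for j in range(k)], dtype=float)
        # cancellation felt by component i: -d_i * sum_{j != i} C_ij d_j
        cancel = -(d * (C @ d - np.diag(C) * d))
        penalty = float(np.max(cancel))
        if penalty < best_penalty - 1e-12:
            best_penalty, best_dirs = penalty, d
    ids = list(sim_matrix.index)
    return [
        (str(ids[i]), effect_size, int(best_dirs[j])) for j, i in enumerate(accepted)
    ]


def generate_responses(
    model: MetabolicModel,
    cohort: Sequence[ExpressionProfile],
    sim_matrix: pd.DataFrame,
    spec: SyntheticSpec,
) -> tuple[DrugResponseTable, GroundTruth]:
    """IC50 vectors linked to planted simulated components (or pure noise).

    For each drug: log10 IC50 = baseline + sum over planted components of
    effect_size * direction * z(simulated value) + N(0, noise_sd); IC50 =
    10**log10IC50 (µM), hence always positive.  With no planting the vector is
    noise only (null data).

    z is the standardized *rank* of the simulated value — a monotone transform
    of it.  Simulated concentrations are heavy-tailed (multiplicative
    cascades), so standardizing the raw values would concentrate the planted
    signal in a few outlier cell lines; rank standardization spreads it across
    the cohort at the stated effect size.
    """
    from scipy import stats

    rng = np.random.default_rng(spec.seed + 3)
    cells = [p.cell_line_id for p in cohort]
    X = sim_matrix[cells]
    table = DrugResponseTable()
    truth = GroundTruth()
    for drug in spec.drugs:
        planted = (spec.planted or {}).get(drug, [])
        log_ic50 = np.full(len(cells), float(rng.normal(0.0, 0.25)))
        for comp_id, effect, direction in planted:
            v = X.loc[comp_id].to_numpy(dtype=float)
            if v.std() <= 0:
                raise ValueError(f"planted component {comp_id!r} is constant in the simulation matrix")
            r = stats.rankdata(v)
            log_ic50 = log_ic50 + effect * direction * (r - r.mean()) / r.std()
        if spec.noise_sd > 0:
            log_ic50 = log_ic50 + rng.normal(0.0, spec.noise_sd, size=len(cells))
        for cl, l in zip(cells, log_ic50):
            table.add(drug, cl, float(10.0**l))
        truth.per_drug[drug] = {c: (e, s) for c, e, s in planted}
    return table, truth


def make_planted_spec(
    spec: SyntheticSpec,
    model: MetabolicModel,
    sim_matrix: pd.DataFrame,
    n_planted: int = 5,
    effect_size: float = 1.5,
) -> SyntheticSpec:
    """Return a copy of ``spec`` with one common planted set for all drugs."""
    rng = np.random.default_rng(spec.seed + 2)
    planted = _choose_planted(model, sim_matrix, n_planted, effect_size, rng)
    return replace(spec, planted={d: list(planted) for d in spec.drugs})


def annotations_from_cohort(cohort: Sequence[ExpressionProfile]) -> dict[str, str]:
    return {p.cell_line_id: p.cancer_type for p in cohort}


def write_dataset(
    outdir: str | Path,
    model: MetabolicModel,
    cohort: Sequence[ExpressionProfile],
    responses: DrugResponseTable,
    truth: GroundTruth,
) -> dict[str, str]:
    """Write model JSON, expression TSV, IC50 CSV, annotation CSV, truth JSON."""
    from .network import save_model
    from .profiles import write_ic50_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    save_model(model, outdir / "model.json")
    files["model"] = "model.json"

    genes = sorted({g for p in cohort for g in p.values})
    expr = pd.DataFrame(
        {p.cell_line_id: [p.values.get(g, 0.0) for g in genes] for p in cohort}, index=genes
    )
    expr.to_csv(outdir / "expression.tsv", sep="\t", index_label="gene", float_format="%.6g")
    files["expression"] = "expression.tsv"

    write_ic50_table(responses, outdir / "ic50.csv")
    files["ic50"] = "ic50.csv"

    ann = pd.DataFrame(
        {"cell_line": [p.cell_line_id for p in cohort], "cancer_type": [p.cancer_type for p in cohort]}
    )
    ann.to_csv(outdir / "annotations.csv", index=False)
    files["annotations"] = "annotations.csv"

    (outdir / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=1) + "\n")
    files["ground_truth"] = "ground_truth.json"
    return files
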