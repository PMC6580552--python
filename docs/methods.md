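# Methods

## The model

`metscreen` simulates cell-line metabolism by *data-flow propagation* over a
pathway-annotated reaction network and screens the simulated state against
drug-response data.

A network consists of components (genes, proteins, compounds, others), each
belonging to one or more pathways (pathway crosstalk is represented purely as
overlapping membership sets — there is no extra edge type), and reactions that
connect reactant components to product components. Each reaction carries a
kinetic law; the implemented law is mass action with a per-reaction rate
constant *k* (the `unit` law is the *k* = 1 special case). One reaction's
contribution to a product is

    contribution(product) = role(product) · k · ∏_r  value(r)^role(r)

where the product runs over the reaction's reactants and `role` is the
stoichiometric weight (exponent on reactants, linear weight on products).
Contributions from all reactions producing the same component are **summed**
(flux additivity).

A simulation of one cell line starts from its gene-expression profile: gene
components take their (probe-aggregated) expression values, every other
component starts at zero. Gene components are then *clamped* as sources and
the network is iterated synchronously:

    x_new = (1 − λ) · x_old + λ · candidate(x_old)

until the maximum absolute change of one sweep falls below a tolerance. On an
acyclic network with λ = 1 this reproduces plain topological data-flow
evaluation exactly (verified against an independent recursive evaluator,
`metscreen.reference`); the damped iteration extends the same semantics to
cyclic networks, where a single topological pass is undefined.
`max_iterations = 1` recovers a single data-flow pass for users who prefer
one-shot evaluation; whether one pass or a fixed point is "the" right
semantics is left configurable because both are defensible readings of
data-flow simulation.

Assumptions worth stating plainly: concentrations are non-negative,
dimensionless abundances (no units, no mass balance, no thermodynamics); the
steady state is a property of the update map, not of an ODE system; genes can
never be overwritten by reactions, even when they appear as products.
Non-convergent cell lines are returned flagged rather than raised, so cohort
runs complete; flagged lines are excluded from the downstream correlation
screen. A non-finite value (true divergence) raises an error naming the
component, iteration and cell line.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `damping` (λ) | 0.5 | step size of the synchronous update, in (0, 1]; 0.5 is a safe contraction for mildly cyclic networks, 1.0 is exact on DAGs |
| `tolerance` | 1e-9 | max-abs change (abundance units) that counts as converged |
| `max_iterations` | 10 000 | hard cap; 1 = single data-flow pass |
| `missing_gene_value` | 0 | abundance for genes absent from a profile |
| `expression_is_log2` | false | exponentiate (2^x) matrices exported on the log2 scale; the simulator is not scale-invariant even though Spearman downstream is |
| `aggregation` | mean | collapse of multiple probes per gene (mean/median/max) |
| `threshold` | 0.15 | minimum absolute Spearman rho for significance |
| `alpha` | 0.05 | family-wise error level after Bonferroni |
| `min_n` | 10 | minimum pairwise-complete pairs for a defined correlation |

## Statistics

For every (component, drug) pair the Spearman rank correlation between the
component's simulated values and the drug's IC50 vector is computed on
pairwise-complete observations (missing IC50s stay masked — CCLE-style panels
do not screen every drug on every line). Ties receive average ranks. The
p-value uses the large-sample *t* approximation for n ≥ 10 and exact
permutation enumeration below that (small-n exact testing is only reachable
by lowering `min_n`, since rank-test approximations degrade there). Constant
simulated vectors (e.g. all-zero components) have undefined rho and are
excluded both from the record set and from the multiplicity family —
including them would silently deflate adjusted p-values.

Bonferroni correction multiplies each p by the family size and caps at 1.
The family defaults to the number of (component, drug) pairs with a defined
rho *in that run* — per-run families are reproducible and are logged in the
run manifest (the bookkeeping invariant: logged tests = defined components ×
drugs). A global `family_size` override exists for users who prefer one
family across strata; neither policy is asserted to be the historically
"correct" one. A record is significant iff |rho| ≥ `threshold` **and**
adjusted p < `alpha`; the magnitude rule is two-sided, and records carry the
sign of rho so reports can distinguish negatively correlated members without
the pipeline interpreting direction biologically.

Per-drug impact summaries count significant components per pathway, counting
a component once in *every* pathway it belongs to (overlap semantics); the
top-5 list is sorted by count descending with ties broken by pathway id for
deterministic output. The impact score is the fraction of all model
components flagged significant for that drug. A cohort's *metabolic
signature* is the intersection of the per-drug significant sets over all
screened drugs — the smallest common set; an empty intersection is a result
(returned with a warning), not an error. Stratified runs repeat the identical
computation on the cell lines of one cancer type, with the family recomputed
inside the stratum.

## The synthetic data generator

The generator stands in for a real expression/pharmacology panel so the whole
pipeline is exercisable offline, at dimensions up to genome scale (3755
components, 4750 reactions, 30 pathways, 479 cell lines over 30 cancer
types, 8 receptor-tyrosine-kinase inhibitors). Defaults for tests are 300
components / 400 reactions / 12 pathways / 120 cell lines — seconds-scale,
but structured enough to exercise pathway overlap and cycles.

*Network.* Genes make up ~20 % of components; every non-gene component gets
at least one producing reaction whose reactants have strictly smaller index,
so the whole network is reachable from gene sources by induction. Reactions
have 1–2 reactants (30 % two-reactant), rate constants U(0.5, 1.5), and 5 %
of reactant roles are 2. Cycles are generated as dedicated two-component
feedback pairs (u → v → u with k = 0.5 each, fed by one upstream component):
every cycle in the network is such a pair with loop gain 0.25, which keeps
the damped iteration contractive by construction. (Free-form back edges were
rejected: a back edge into a multiplicative cascade can acquire loop gain > 1
through high-magnitude paths and diverge.)

*Expression.* Gene values are log-normal: exp(baseline_g + shift_{type,g} +
ε), with per-gene baseline N(0, 0.5), per-cancer-type shift N(0, 0.25) and
per-line noise N(0, 0.5) on the natural-log scale; cell lines are assigned
round-robin to cancer types. Zero line-level noise makes all lines of a type
identical, which several tests exploit.

*Responses.* For each drug, log10 IC50 = baseline + Σ effect·direction·z +
N(0, noise_sd), exponentiated so IC50 > 0 (µM). z is the standardized
**rank** of the planted component's simulated value — a monotone transform of
it. Simulated concentrations are heavy-tailed (multiplicative cascades), so
standardizing raw values would concentrate the planted signal in a few
outlier lines and hide it from a rank screen; rank standardization spreads
the stated effect size across the cohort.

*Identifiability of the planted truth.* Planted components are sampled among
non-gene, non-constant components subject to pairwise |Spearman rho| <
max(0.15, 2/√n) — never below the sampling floor of correlations between
independent vectors — and the ±1 direction vector is the one (over all 2^k
assignments) minimizing the worst signed cross-correlation working against
any single component. Without this, two network components sharing upstream
drivers can be planted with opposing signs and cancel, leaving a "planted"
component with no recoverable marginal association; the constraint is a
well-posedness requirement of the ground truth, not a change to effect size,
noise, or any screening knob.

What the generator does **not** emulate: probe-level microarray artifacts,
dose–response curve fitting and IC50 censoring at screening ceilings, batch
effects, uneven cancer-type panel sizes, and any biologically meaningful
network topology. Passing the planted-recovery and null-control checks
therefore demonstrates that the pipeline's statistics behave as designed on
data satisfying its assumptions — not that the biological conclusions drawn
from any real panel are correct.

## Numerical and design notes

- Determinism: all generators draw from `numpy.random.default_rng(seed)`;
  identical configs give bit-identical simulation states and byte-identical
  output TSVs (numbers are written with 6 significant digits).
- The engine and the recursive reference evaluator agree on acyclic networks
  to machine precision; occasional 1-ulp relative differences exist because
  numpy's vectorized `pow` and the scalar libm `pow` round differently.
- Ties in top-pathway ranking break by pathway id; drug order follows first
  appearance in the IC50 file; signature members are sorted by component id.
- Cell-line id matching is exact after whitespace trimming — no fuzzy
  matching, on the grounds that silent mismatches are worse than loud ones.
- IC50 values are used as given (no ceiling truncation); Spearman is
  invariant to monotone transforms, and ties at a ceiling fall under the
  average-rank rule.
- Degenerate inputs: an empty expression profile yields the all-zero fixed
  point in one iteration; a drug whose response vector is constant within a
  stratum has every correlation undefined for that stratum.

## Known limitations

- Tissue-stratified signatures at genome scale are underpowered with ~16
  lines per type: the Bonferroni bar at a ~30 000-test family and n = 16
  sits near |rho| ≈ 0.9, so strict per-tissue signatures come out empty
  (driver `analysis/04` reports this explicitly). Meaningful per-tissue
  screens need larger strata or a smaller test family.
- The mass-action data-flow law is the minimal multiplicative law; it is not
  calibrated kinetics, and simulated magnitudes have no physical units.
- Bonferroni is deliberately conservative; no FDR alternative is provided.

## Problem sizes used by the packaged checks

The test suite and `scripts/acceptance.py` run the oracle comparison on 100
random acyclic networks of ≤ 30 reactions, the Spearman cross-check on 10 000
sampled permutation pairs (n ≤ 6), planted-signature recovery at 300
components / 400 reactions / 200 cell lines / 8 drugs / 5 planted components
(effect 1.5, noise 0.5) over 10 seeds, and the null false-positive control at
the same scale over 20 seeds. The analysis drivers run the full study scale
(3755 / 4750 / 30 pathways, 479 lines, 30 types).
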