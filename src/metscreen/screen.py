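"""Correlation screen of simulated metabolism against drug sensitivity.

For each (component, drug) pair the Spearman rank correlation between the
component's simulated values and the drug's IC50 vector is computed on
pairwise-complete observations, Bonferroni-corrected over the whole run, and
flagged significant when |rho| >= threshold AND adjusted p < alpha.  Per-drug
impact summaries count significant components per pathway (overlap counted in
every pathway); a cohort's metabolic signature is the common significant
component set across all screened drugs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import MetabolicModel
from .profiles import Cohort

DEFAULT_THRESHOLD = 0.15
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_N = 10


class SpearmanResult(NamedTuple):
    rho: float | None
    p_value: float | None
    n_pairs: int


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=-1)


def _pearson_on_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if denom == 0.0:
        return math.nan
    return float(rxc @ ryc) / denom


def _approx_p(rho: float, n: int) -> float:
    """Two-sided p from the large-sample t approximation (df = n - 2)."""
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p by full enumeration (intended for n < 10)."""
    n = len(ry)
    rxc = rx - rx.mean()
    denom_x = float(rxc @ rxc)
    ryc = ry - ry.mean()
    denom = math.sqrt(denom_x * float(ryc @ ryc))
    count = 0
    total = 0
    thr = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(rxc @ ryc[list(perm)]) / denom
        if abs(r) >= thr:
            count += 1
        total += 1
    return count / total


def spearman_correlation(
    x: Sequence[float],
    y: Sequence[float],
    min_n: int = DEFAULT_MIN_N,
) -> SpearmanResult:
    """Spearman rho on pairwise-complete pairs with average ranks for ties.

    p comes from the large-sample t approximation for n >= 10 and from exact
    permutation enumeration below that.  rho is None (undefined) when fewer
    than ``min_n`` complete pairs remain or either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(keep.sum())
    if n < max(min_n, 2):
        return SpearmanResult(None, None, n)
    rx, ry = _rank(x), _rank(y)
    rho = _pearson_on_ranks(rx, ry)
    if math.isnan(rho):  # constant vector
        return SpearmanResult(None, None, n)
    p = _approx_p(rho, n) if n >= 10 else _exact_p(rx, ry, rho)
    return SpearmanResult(rho, p, n)


def bonferroni_adjust(p_values: Sequence[float | None], family_size: int) -> list[float | None]:
    """p_adj = min(1, p * family_size); None/NaN entries pass through undefined."""
    if family_size < 1:
        raise ValueError(f"family_size must be >= 1, got {family_size}")
    n_defined = sum(1 for p in p_values if p is not None and not (isinstance(p, float) and math.isnan(p)))
    if family_size < n_defined:
        raise ValueError(f"family_size {family_size} < number of defined p-values {n_defined}")
    out: list[float | None] = []
    for p in p_values:
        if p is None or (isinstance(p, float) and math.isnan(p)):
            out.append(None)
        else:
            out.append(min(1.0, float(p) * family_size))
    return out


@dataclass(frozen=True)
class CorrelationRecord:
    component_id: str
    drug: str
    rho: float
    p_value: float
    p_adjusted: float
    n_pairs: int
    significant: bool


@dataclass
class ScreenResult:
    """All defined correlation records of one run plus family bookkeeping."""

    records: list[CorrelationRecord]
    family_size: int
    n_tests: int  # number of computed (defined) correlations
    n_undefined: int
    threshold: float
    alpha: float

    def by_drug(self) -> dict[str, list[CorrelationRecord]]:
        out: dict[str, list[CorrelationRecord]] = {}
        for rec in self.records:
            out.setdefault(rec.drug, []).append(rec)
        return out

    def significant_components(self, drug: str) -> set[str]:
        return {r.component_id for r in self.records if r.drug == drug and r.significant}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.component_id, r.drug, r.rho, r.p_value, r.p_adjusted, r.n_pairs, r.significant)
                for r in self.records
            ],
            columns=["component", "drug", "rho", "p", "p_adj", "n", "significant"],
        )


def screen_components(
    sim_matrix: pd.DataFrame,
    cohort: Cohort,
    drugs: Sequence[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    min_n: int = DEFAULT_MIN_N,
    family_size: int | None = None,
    cell_lines: Sequence[str] | None = None,
) -> ScreenResult:
    """Correlate every component row against every drug's IC50 vector.

    The Bonferroni family defaults to the number of (component, drug) pairs
    with a defined rho in this run; ``family_size`` overrides it (global
    family policy).  ``cell_lines`` restricts the run to a stratum.
    """
    drugs = list(drugs) if drugs is not None else list(cohort.drugs)
    if not drugs:
        raise ValueError("no drugs to screen")
    cells = list(cell_lines) if cell_lines is not None else list(cohort.cell_lines)
    missing = [c for c in cells if c not in sim_matrix.columns]
    if missing:
        raise ValueError(f"simulation matrix lacks columns for cell lines: {missing[:5]}")
    X = sim_matrix[cells].to_numpy(dtype=float)

    raw: list[tuple[str, str, float, float, int]] = []
    n_undefined = 0
    for drug in drugs:
        y = cohort.responses.loc[drug, cells].to_numpy(dtype=float)
        obs = np.isfinite(y)
        n = int(obs.sum())
        if n < max(min_n, 2):
            n_undefined += X.shape[0]
            continue
        Xo = X[:, obs]
        ry = _rank(y[obs])
        ryc = ry - ry.mean()
        y_ss = float(ryc @ ryc)
        if y_ss == 0.0:  # constant response: rho undefined for every component
            n_undefined += X.shape[0]
            continue
        rx = _rank(Xo)
        rxc = rx - rx.mean(axis=1, keepdims=True)
        x_ss = np.einsum("ij,ij->i", rxc, rxc)
        defined = x_ss > 0.0
        n_undefined += int((~defined).sum())
        denom = np.sqrt(x_ss[defined] * y_ss)
        rho = (rxc[defined] @ ryc) / denom
        rho = np.clip(rho, -1.0, 1.0)
        comp_ids = np.asarray(sim_matrix.index)[defined]
        if n >= 10:
            with np.errstate(divide="ignore", invalid="ignore"):
                t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
            p = np.where(np.abs(rho) >= 1.0, 0.0, p)
        else:
            p = np.array([_exact_p(rx_i, ry, r) for rx_i, r in zip(rx[defined], rho)])
        for cid, r_i, p_i in zip(comp_ids, rho, p):
            raw.append((str(cid), drug, float(r_i), float(p_i), n))

    n_tests = len(raw)
    fam = family_size if family_size is not None else max(n_tests, 1)
    if fam < n_tests:
        raise ValueError(f"family_size {fam} < number of defined correlations {n_tests}")
    if n_tests == 0:
        warnings.warn("no defined correlations in this run (all-constant matrix?)", stacklevel=2)

    records = []
    for cid, drug, rho_i, p_i, n in raw:
        p_adj = min(1.0, p_i * fam)
        sig = (abs(rho_i) >= threshold) and (p_adj < alpha)
        records.append(CorrelationRecord(cid, drug, rho_i, p_i, p_adj, n, sig))
    return ScreenResult(records, fam, n_tests, n_undefined, threshold, alpha)


@dataclass(frozen=True)
class DrugImpactSummary:
    drug: str
    n_significant_components: int
    affected_pathways: frozenset[str]
    top_pathways: tuple[tuple[str, int], ...]  # (pathway id, count), length <= 5
    impact_score: float
    affected_by_class: dict[str, int] = field(default_factory=dict)


def summarize_drug(
    records: Iterable[CorrelationRecord],
    model: MetabolicModel,
    drug: str | None = None,
    top_k: int = 5,
) -> DrugImpactSummary:
    """Pathway-level impact of one drug's significant components.

    A component in k pathways is counted in each of them; impact score is the
    fraction of all model components flagged significant.
    """
    records = list(records)
    drugs = {r.drug for r in records}
    if drug is None:
        if len(drugs) > 1:
            raise ValueError(f"records span several drugs: {sorted(drugs)}")
        drug = next(iter(drugs)) if drugs else ""
    elif drugs - {drug}:
        raise ValueError(f"records for {sorted(drugs - {drug})} mixed into summary for {drug!r}")

    comp_index = model.component_index
    sig_components = {r.component_id for r in records if r.significant}
    counts: dict[str, int] = {}
    for cid in sig_components:
        comp = comp_index.get(cid)
        if comp is None:
            continue
        for pw in comp.pathways:
            counts[pw] = counts.get(pw, 0) + 1
    affected = frozenset(counts)
    top = tuple(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k])

    classes: dict[str, int] = {}
    class_of = {p.id: p.pathway_class for p in model.pathways}
    for pw in affected:
        label = class_of.get(pw) or "unclassified"
        classes[label] = classes.get(label, 0) + 1

    n_total = len(model.components)
    impact = len(sig_components) / n_total if n_total else 0.0
    return DrugImpactSummary(drug, len(sig_components), affected, top, impact, classes)


@dataclass(frozen=True)
class SignatureMember:
    component_id: str
    rho_by_drug: dict[str, float]
    max_p_adjusted: float
    pathways: frozenset[str]


@dataclass
class MetabolicSignature:
    """Common significant component set across every screened drug."""

    cohort_label: str
    drugs: tuple[str, ...]
    members: list[SignatureMember]

    def component_ids(self) -> set[str]:
        return {m.component_id for m in self.members}

    def pathways(self) -> set[str]:
        out: set[str] = set()
        for m in self.members:
            out |= m.pathways
        return out

    def frame(self) -> pd.DataFrame:
        rows = []
        for m in sorted(self.members, key=lambda m: m.component_id):
            row = {"component": m.component_id, "max_p_adj": m.max_p_adjusted,
                   "pathways": ";".join(sorted(m.pathways))}
            for d in self.drugs:
                row[f"rho_{d}"] = m.rho_by_drug.get(d)
            rows.append(row)
        return pd.DataFrame(rows)


def extract_signature(
    records_by_drug: Mapping[str, Iterable[CorrelationRecord]] | ScreenResult,
    drugs: Sequence[str],
    cohort_label: str = "all",
    model: MetabolicModel | None = None,
) -> MetabolicSignature:
    """Intersect the per-drug significant sets; empty intersections are allowed."""
    if not drugs:
        raise ValueError("drugs must be non-empty")
    if isinstance(records_by_drug, ScreenResult):
        records_by_drug = records_by_drug.by_drug()
    missing = [d for d in drugs if d not in records_by_drug]
    if missing:
        raise ValueError(f"no records for drugs: {missing}")

    per_drug: dict[str, dict[str, CorrelationRecord]] = {}
    for d in drugs:
        per_drug[d] = {r.component_id: r for r in records_by_drug[d] if r.significant}
    common = set.intersection(*(set(per_drug[d]) for d in drugs))
    if not common:
        warnings.warn(f"empty signature for cohort {cohort_label!r}", stacklevel=2)

    comp_index = model.component_index if model is not None else {}
    members = []
    for cid in sorted(common):
        rho_by_drug = {d: per_drug[d][cid].rho for d in drugs}
        max_p = max(per_drug[d][cid].p_adjusted for d in drugs)
        pw = comp_index[cid].pathways if cid in comp_index else frozenset()
        members.append(SignatureMember(cid, rho_by_drug, max_p, pw))
    return MetabolicSignature(cohort_label, tuple(drugs), members)


@dataclass
class StratifiedResult:
    cancer_type: str
    cell_lines: list[str]
    screen: ScreenResult
    summaries: dict[str, DrugImpactSummary]
    signature: MetabolicSignature


def stratified_run(
    sim_matrix: pd.DataFrame,
    cohort: Cohort,
    cancer_type: str,
    model: MetabolicModel,
    drugs: Sequence[str] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    min_n: int = DEFAULT_MIN_N,
    family_size: int | None = None,
) -> StratifiedResult:
    """The full screen restricted to one cancer type ('all' = whole cohort).

    The Bonferroni family is recomputed within the stratum unless a global
    ``family_size`` override is supplied.
    """
    cells = cohort.cells_of_type(cancer_type)
    if len(cells) < min_n:
        raise ValueError(
            f"stratum {cancer_type!r} has {len(cells)} cell lines, fewer than min_n={min_n}"
        )
    drugs = list(drugs) if drugs is not None else list(cohort.drugs)
    screen = screen_components(
        sim_matrix, cohort, drugs, threshold, alpha, min_n, family_size, cell_lines=cells
    )
    grouped = screen.by_drug()
    summaries = {d: summarize_drug(grouped.get(d, []), model, drug=d) for d in drugs}
    signature = extract_signature(
        {d: grouped.get(d, []) for d in drugs}, drugs, cohort_label=cancer_type, model=model
    )
    return StratifiedResult(cancer_type, cells, screen, summaries, signature)
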