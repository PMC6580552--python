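import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from metscreen.network import Component, MetabolicModel, Pathway
from metscreen.screen import (
    CorrelationRecord,
    bonferroni_adjust,
    extract_signature,
    screen_components,
    spearman_correlation,
    stratified_run,
    summarize_drug,
)


def exact_spearman(x, y):
    """Independent oracle: Pearson correlation of average ranks in exact
    rational arithmetic."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [Fraction(0)] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = Fraction(i + j + 2, 2)  # average of 1-based positions i+1..j+1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx = sum(rx, Fraction(0)) / n
    my = sum(ry, Fraction(0)) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den2 = sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    if den2 == 0:
        return None
    return float(num) / math.sqrt(float(den2))


class TestSpearman:
    @pytest.mark.parametrize(
        "x, y, rho",
        [
            ((1, 2, 3), (10, 20, 30), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4, 5), (2, 1, 4, 3, 5), 0.8),
        ],
    )
    def test_worked_examples(self, x, y, rho):
        result = spearman_correlation(x, y, min_n=2)
        assert result.rho == pytest.approx(rho, abs=1e-15)
        assert result.n_pairs == len(x)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_all_permutations_match_exact_rank_oracle(self, n):
        x = list(range(1, n + 1))
        for perm in itertools.permutations(x):
            got = spearman_correlation(x, perm, min_n=2).rho
            assert got == pytest.approx(exact_spearman(x, perm), abs=1e-15)

    def test_ties_use_average_ranks(self):
        x = [1.0, 1.0, 2.0, 3.0]
        y = [5.0, 6.0, 6.0, 8.0]
        got = spearman_correlation(x, y, min_n=2)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert got.rho == pytest.approx(exact_spearman(x, y), abs=1e-12)
        assert got.rho == pytest.approx(ref_rho, abs=1e-12)

    def test_large_sample_p_matches_t_approximation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        got = spearman_correlation(x, y)
        ref_rho, ref_p = stats.spearmanr(x, y)
        assert got.rho == pytest.approx(ref_rho, abs=1e-12)
        assert got.p_value == pytest.approx(ref_p, rel=1e-9)

    def test_exact_small_n_p_is_permutation_fraction(self):
        # n=4, x and y perfectly concordant: only 1 of 24 permutations
        # reaches |rho| = 1 on each side -> two-sided p = 2/24
        got = spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40], min_n=2)
        assert got.p_value == pytest.approx(2 / 24)

    def test_pairwise_complete_drops_masked_pairs(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, np.nan, 3.0, 8.0, 10.0]
        got = spearman_correlation(x, y, min_n=2)
        assert got.n_pairs == 3
        assert got.rho == pytest.approx(1.0)

    def test_constant_vector_is_undefined(self):
        got = spearman_correlation([1.0] * 12, list(range(12)))
        assert got.rho is None and got.p_value is None

    def test_below_min_n_is_undefined(self):
        got = spearman_correlation([1, 2, 3], [3, 1, 2], min_n=10)
        assert got.rho is None and got.n_pairs == 3

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length mismatch"):
            spearman_correlation([1, 2], [1, 2, 3])

    @given(
        xy=st.lists(
            st.tuples(st.integers(-1000, 1000), st.integers(-1000, 1000)),
            min_size=12,
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_strictly_increasing_transform(self, xy):
        x = [float(a) for a, _ in xy]
        y = [float(b) for _, b in xy]
        base = spearman_correlation(x, y)
        transformed = spearman_correlation(x, [3.0 * v + 7.0 for v in y])
        if base.rho is None:
            assert transformed.rho is None
        else:
            assert transformed.rho == pytest.approx(base.rho, abs=1e-12)


class TestBonferroni:
    def test_multiply_and_cap(self):
        assert bonferroni_adjust([0.001], 100) == [pytest.approx(0.1)]
        assert bonferroni_adjust([0.5], 10) == [1.0]

    def test_family_of_one_is_identity(self):
        assert bonferroni_adjust([0.3], 1) == [pytest.approx(0.3)]

    def test_undefined_entries_pass_through(self):
        out = bonferroni_adjust([0.01, None], 10)
        assert out == [pytest.approx(0.1), None]

    def test_bad_family_size_raises(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1], 0)
        with pytest.raises(ValueError):
            bonferroni_adjust([0.1, 0.2, 0.3], 2)


def _tiny_model(component_pathways):
    comps = tuple(
        Component(cid, pathways=frozenset(pws)) for cid, pws in component_pathways.items()
    )
    pws = tuple(Pathway(p) for p in sorted({p for v in component_pathways.values() for p in v}))
    return MetabolicModel(comps, (), pws)


def _rec(cid, drug, rho, p_adj, sig):
    return CorrelationRecord(cid, drug, rho, p_adj, p_adj, 100, sig)


class TestSignificanceRule:
    def test_screen_flags_match_rule_on_real_run(self, planted_dataset):
        """|rho| >= 0.15 in absolute value AND Bonferroni-adjusted p < alpha."""
        res = screen_components(planted_dataset["sim_matrix"], planted_dataset["cohort"])
        for r in res.records:
            assert r.significant == ((abs(r.rho) >= 0.15) and (r.p_adjusted < 0.05))
            assert r.p_adjusted >= r.p_value
        # negative correlations pass the absolute-value rule too
        assert any(r.significant and r.rho < 0 for r in res.records)

    def test_significance_monotone_in_threshold_and_alpha(self, planted_dataset):
        strict = screen_components(
            planted_dataset["sim_matrix"], planted_dataset["cohort"], threshold=0.2, alpha=0.01
        )
        loose = screen_components(
            planted_dataset["sim_matrix"], planted_dataset["cohort"], threshold=0.1, alpha=0.05
        )
        for d in planted_dataset["cohort"].drugs:
            assert strict.significant_components(d) <= loose.significant_components(d)

    def test_test_count_accounting(self, planted_dataset):
        res = screen_components(planted_dataset["sim_matrix"], planted_dataset["cohort"])
        cohort = planted_dataset["cohort"]
        X = planted_dataset["sim_matrix"][cohort.cell_lines].to_numpy()
        n_defined = int((X.std(axis=1) > 0).sum())
        assert res.n_tests == n_defined * len(cohort.drugs)
        assert res.family_size == res.n_tests


class TestSummarizeDrug:
    def test_impact_score_is_significant_over_total(self):
        model = _tiny_model({f"c{i}": ["pw0"] for i in range(10)})
        records = [_rec(f"c{i}", "d", 0.3, 0.001, i < 4) for i in range(10)]
        s = summarize_drug(records, model)
        assert s.impact_score == pytest.approx(4 / 10)
        assert s.n_significant_components == 4

    def test_zero_significant_gives_empty_summary(self):
        model = _tiny_model({"c0": ["pw0"]})
        s = summarize_drug([_rec("c0", "d", 0.01, 0.9, False)], model)
        assert s.impact_score == 0.0
        assert s.top_pathways == ()
        assert s.affected_pathways == frozenset()

    def test_top_pathways_sorted_by_count_then_id(self):
        member = {}
        for i in range(5):
            member[f"a{i}"] = ["P1"]
        for i in range(3):
            member[f"b{i}"] = ["P2"]
        for i in range(3):
            member[f"c{i}"] = ["P3"]
        model = _tiny_model(member)
        records = [_rec(cid, "d", 0.5, 0.001, True) for cid in member]
        s = summarize_drug(records, model)
        assert s.top_pathways == (("P1", 5), ("P2", 3), ("P3", 3))

    def test_overlapping_component_counted_in_each_pathway(self):
        model = _tiny_model({"c0": ["P1", "P2"]})
        s = summarize_drug([_rec("c0", "d", 0.5, 0.001, True)], model)
        assert dict(s.top_pathways) == {"P1": 1, "P2": 1}

    def test_mixed_drugs_rejected(self):
        model = _tiny_model({"c0": ["P1"]})
        with pytest.raises(ValueError, match="several drugs"):
            summarize_drug([_rec("c0", "d1", 0.5, 0.01, True), _rec("c0", "d2", 0.5, 0.01, True)], model)


class TestExtractSignature:
    def test_intersection_of_significant_sets(self):
        by_drug = {
            "d1": [_rec(c, "d1", 0.5, 0.001, c in {"A", "B", "C"}) for c in "ABCD"],
            "d2": [_rec(c, "d2", -0.5, 0.001, c in {"B", "C", "D"}) for c in "ABCD"],
        }
        sig = extract_signature(by_drug, ["d1", "d2"])
        assert sig.component_ids() == {"B", "C"}

    def test_single_drug_signature_is_its_significant_set(self):
        by_drug = {"d1": [_rec(c, "d1", 0.5, 0.001, c in {"A", "C"}) for c in "ABC"]}
        sig = extract_signature(by_drug, ["d1"])
        assert sig.component_ids() == {"A", "C"}

    def test_disjoint_sets_give_empty_signature_with_warning(self):
        by_drug = {
            "d1": [_rec("A", "d1", 0.5, 0.001, True)],
            "d2": [_rec("B", "d2", 0.5, 0.001, True)],
        }
        with pytest.warns(UserWarning, match="empty signature"):
            sig = extract_signature(by_drug, ["d1", "d2"])
        assert sig.members == []

    def test_adding_a_drug_never_enlarges_the_signature(self, planted_dataset):
        res = screen_components(planted_dataset["sim_matrix"], planted_dataset["cohort"])
        drugs = planted_dataset["cohort"].drugs
        smaller = extract_signature(res, drugs[:4])
        larger = extract_signature(res, drugs)
        assert larger.component_ids() <= smaller.component_ids()
        for d in drugs:
            assert larger.component_ids() <= res.significant_components(d)

    def test_members_carry_per_drug_rho_and_sign(self, planted_dataset):
        res = screen_components(planted_dataset["sim_matrix"], planted_dataset["cohort"])
        drugs = planted_dataset["cohort"].drugs
        sig = extract_signature(res, drugs, model=planted_dataset["model"])
        truth = planted_dataset["truth"]
        for m in sig.members:
            assert set(m.rho_by_drug) == set(drugs)
            if m.component_id in truth.common_components():
                for d in drugs:
                    effect, direction = truth.per_drug[d][m.component_id]
                    assert math.copysign(1, m.rho_by_drug[d]) == direction

    def test_empty_drug_list_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            extract_signature({}, [])


class TestStratifiedRun:
    def test_all_stratum_equals_unstratified_screen(self, planted_dataset):
        model = planted_dataset["model"]
        res = screen_components(planted_dataset["sim_matrix"], planted_dataset["cohort"])
        strat = stratified_run(
            planted_dataset["sim_matrix"], planted_dataset["cohort"], "all", model
        )
        assert strat.screen.records == res.records
        assert strat.screen.family_size == res.family_size

    def test_too_small_stratum_errors_with_name(self, planted_dataset):
        with pytest.raises(ValueError, match="nosuchtype.*min_n"):
            stratified_run(
                planted_dataset["sim_matrix"],
                planted_dataset["cohort"],
                "nosuchtype",
                planted_dataset["model"],
            )

    def test_strata_computed_independently_of_pool(self, planted_dataset):
        model = planted_dataset["model"]
        cohort = planted_dataset["cohort"]
        breast = stratified_run(planted_dataset["sim_matrix"], cohort, "breast", model)
        # recompute directly on the stratum's cell lines
        direct = screen_components(
            planted_dataset["sim_matrix"], cohort, cell_lines=cohort.cells_of_type("breast")
        )
        assert breast.screen.records == direct.records
        # per-stratum family differs from the pooled family in general
        pooled = screen_components(planted_dataset["sim_matrix"], cohort)
        assert breast.screen.n_tests <= pooled.n_tests
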