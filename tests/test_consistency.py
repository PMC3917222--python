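"""Consistency ranking, overlap statistics, controls, similarity test."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nitronet.consistency import (
    SimilarityTable,
    consistency_ranking,
    cross_experiment_similarity_test,
    evaluate_simulated_terms,
    level_distribution_control,
    overlap_curves,
    pairwise_shared_terms,
    random_list_annotation_control,
    shared_fraction,
    shared_term_gene_overlap,
)
from nitronet.synthetic import simulate_shared_terms


class TestConsistencyRanking:
    def test_ordering_keys(self):
        # counts (3, 2, 2, 1); ties resolved by up count then gene id
        sets = {
            "e1": {"up": {"a", "b", "c", "d"}, "down": set()},
            "e2": {"up": {"a", "b"}, "down": {"c"}},
            "e3": {"up": {"a"}, "down": {"b"}},
        }
        df = consistency_ranking(sets)
        assert list(df["gene"]) == ["a", "b", "c", "d"]
        assert list(df["total"]) == [3, 3, 2, 1]
        assert list(df["up"]) == [3, 2, 1, 1]

    def test_unregulated_gene_absent(self):
        df = consistency_ranking({"e1": {"up": {"a"}, "down": set()}})
        assert set(df["gene"]) == {"a"}

    def test_empty_input_empty_output(self):
        assert consistency_ranking({}).empty


class TestSharedFraction:
    def test_identical_sets(self):
        assert shared_fraction([{"a", "b"}, {"a", "b"}]) == 100.0

    def test_disjoint_sets(self):
        assert shared_fraction([{"a"}, {"b"}, {"c"}]) == 0.0

    def test_jaccard_value(self):
        assert shared_fraction([{"a", "b", "c"}, {"b", "c", "d"}]) == 50.0

    def test_intersection_over_mean_metric(self):
        val = shared_fraction([{"a", "b", "c"}, {"b", "c", "d"}],
                              metric="intersection_over_mean")
        assert val == pytest.approx(100.0 * 2 / 3)

    def test_empty_union_zero(self):
        assert shared_fraction([set(), set()]) == 0.0

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            shared_fraction([{"a"}])

    def test_permutation_invariant(self):
        sets = [{"a", "b"}, {"b", "c"}, {"b"}]
        assert shared_fraction(sets) == shared_fraction(sets[::-1])


class TestOverlapCurves:
    def test_exhaustive_combination_counts(self):
        from math import comb
        gene_sets = {f"e{i}": {f"g{i}"} for i in range(4)}
        term_sets = {f"e{i}": {"t"} for i in range(4)}
        curves = overlap_curves(gene_sets, term_sets, max_combos=10**6, seed=0)
        for _, row in curves.iterrows():
            assert row["n_combinations_evaluated"] == comb(4, int(row["m"]))
            assert not row["sampled"]

    def test_sampling_branch_flagged(self):
        gene_sets = {f"e{i}": {f"g{i}"} for i in range(8)}
        term_sets = {f"e{i}": {"t"} for i in range(8)}
        curves = overlap_curves(gene_sets, term_sets, max_combos=10, seed=0)
        mid = curves[curves["m"] == 4].iloc[0]
        assert mid["sampled"] and mid["n_combinations_evaluated"] == 10

    def test_identical_sets_coincide(self):
        sets = {f"e{i}": {"x", "y"} for i in range(3)}
        curves = overlap_curves(sets, sets, seed=0)
        assert np.allclose(curves["gene_overlap_pct"], 100.0)
        assert np.allclose(curves["go_overlap_pct"], 100.0)

    def test_single_experiment_rejected(self):
        with pytest.raises(ValueError):
            overlap_curves({"e": set()}, {"e": set()})


class TestLevelControl:
    def test_shared_equals_total_distance_zero(self):
        terms = {"e1": {"a", "b"}, "e2": {"a", "b"}}
        shared = pairwise_shared_terms(terms)
        ctl = level_distribution_control(terms, shared, {"a": 3, "b": 7})
        assert ctl.tv_distance == pytest.approx(0.0)
        assert not ctl.flagged_empty

    def test_empty_shared_flagged(self):
        terms = {"e1": {"a"}, "e2": {"b"}}
        ctl = level_distribution_control(terms, pairwise_shared_terms(terms),
                                         {"a": 3, "b": 7})
        assert ctl.flagged_empty and np.isnan(ctl.tv_distance)


class TestRandomListControl:
    def test_private_terms_give_exact_counts(self, rng):
        # every gene carries exactly one private term
        universe = [f"g{i}" for i in range(30)]
        ann = {g: {f"t_{g}"} for g in universe}
        ctl = random_list_annotation_control(universe, ann, list_size=10,
                                            n_iter=20, seed=0)
        assert ctl.mean == 10.0 and ctl.sd == 0.0

    def test_reproducible_single_draw(self):
        universe = [f"g{i}" for i in range(50)]
        ann = {g: {f"t{i % 7}"} for i, g in enumerate(universe)}
        a = random_list_annotation_control(universe, ann, 5, n_iter=1, seed=9)
        b = random_list_annotation_control(universe, ann, 5, n_iter=1, seed=9)
        assert a.counts.tolist() == b.counts.tolist()

    def test_mean_matches_inclusion_exclusion_expectation(self, rng):
        # E[#distinct terms] = sum_t 1 - C(N - n_t, s) / C(N, s)
        from math import comb
        universe = [f"g{i}" for i in range(50)]
        terms = [f"t{j}" for j in range(8)]
        ann = {g: set(rng.choice(terms, size=2, replace=False)) for g in universe}
        s = 12
        n_t = {t: sum(t in ann[g] for g in universe) for t in terms}
        expected = sum(1 - comb(50 - n, s) / comb(50, s) for n in n_t.values())
        ctl = random_list_annotation_control(universe, ann, list_size=s,
                                            n_iter=4000, seed=1)
        assert ctl.mean == pytest.approx(expected, abs=3 * ctl.sd / np.sqrt(4000) + 0.05)

    def test_oversized_list_rejected(self):
        with pytest.raises(ValueError):
            random_list_annotation_control(["a"], {"a": set()}, 2)

    def test_observed_quantile_reported(self):
        universe = [f"g{i}" for i in range(30)]
        ann = {g: {f"t_{g}"} for g in universe}
        ctl = random_list_annotation_control(universe, ann, 10, n_iter=50,
                                            seed=0, observed_genes=set(universe[:10]))
        assert ctl.observed == 10
        assert 0.0 <= ctl.observed_quantile <= 1.0


class TestSharedTermGeneOverlap:
    T2G = {"T": {"g1", "g2", "g3"}}

    def test_identical_contributors(self):
        res = shared_term_gene_overlap(
            {("e1", "e2"): {"T"}},
            {"e1": {"g1", "g2"}, "e2": {"g1", "g2"}}, self.T2G)
        assert res.grand_mean_pct == 100.0

    def test_disjoint_contributors(self):
        res = shared_term_gene_overlap(
            {("e1", "e2"): {"T"}}, {"e1": {"g1"}, "e2": {"g2"}}, self.T2G)
        assert res.grand_mean_pct == 0.0

    def test_partial_overlap_value(self):
        # exp1 contributes {g1, g2}, exp2 contributes {g2, g3} -> 1/3
        res = shared_term_gene_overlap(
            {("e1", "e2"): {"T"}},
            {"e1": {"g1", "g2"}, "e2": {"g2", "g3"}}, self.T2G)
        assert res.grand_mean_pct == pytest.approx(100.0 / 3)

    def test_no_shared_terms_flagged(self):
        res = shared_term_gene_overlap({}, {}, self.T2G)
        assert res.flagged_empty and np.isnan(res.grand_mean_pct)


class TestSimilarityTest:
    def make_sim(self, pairs):
        rows = [(a, b, s) for (a, b), s in pairs.items()]
        rows += [(b, a, s) for (a, b), s in pairs.items()]
        return SimilarityTable(pd.DataFrame(rows, columns=["gene_a", "gene_b",
                                                           "score"]))

    def test_constant_similarity_not_significant(self):
        genes = [f"g{i}" for i in range(8)]
        sim = self.make_sim({(a, b): 1.0
                             for a, b in itertools.combinations(genes, 2)})
        res = cross_experiment_similarity_test(
            "T", {"e1": set(genes[:3]), "e2": set(genes[3:6])}, sim,
            set(genes), n_perm=200, seed=0)
        assert not res.significant and not res.skipped

    def test_single_cross_pair_skipped(self):
        sim = self.make_sim({})
        res = cross_experiment_similarity_test(
            "T", {"e1": {"a"}, "e2": {"b"}}, sim, {"a", "b", "c"},
            n_perm=50, seed=0)
        assert res.skipped and "cross-experiment" in res.skip_reason

    def test_too_few_annotated_skipped(self):
        res = cross_experiment_similarity_test(
            "T", {"e1": {"a"}, "e2": {"a"}}, self.make_sim({}), {"a"},
            n_perm=50, seed=0)
        assert res.skipped and "annotated" in res.skip_reason

    def test_absent_pairs_score_zero(self):
        sim = self.make_sim({("a", "b"): 0.9})
        assert sim.score("a", "b") == 0.9
        assert sim.score("a", "zz") == 0.0
        assert sim.score("a", "a") == 1.0

    def test_planted_degeneracy_detected(self):
        terms = simulate_shared_terms(30, mode="planted", seed=4)
        frac = evaluate_simulated_terms(terms, n_perm=300, seed=5)
        assert frac >= 0.8

    def test_exchangeable_null_near_alpha(self):
        terms = simulate_shared_terms(150, mode="null", seed=6)
        frac = evaluate_simulated_terms(terms, n_perm=300, alpha=0.05, seed=7)
        assert frac <= 0.10

    def test_deterministic_under_seed(self):
        terms = simulate_shared_terms(3, mode="planted", seed=1)
        t = terms[0]
        r1 = cross_experiment_similarity_test(
            t.term, t.contributors, SimilarityTable(t.similarity), t.annotated,
            n_perm=100, seed=11)
        r2 = cross_experiment_similarity_test(
            t.term, t.contributors, SimilarityTable(t.similarity), t.annotated,
            n_perm=100, seed=11)
        assert r1 == r2
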