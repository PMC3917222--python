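"""Adjacency, topological overlap, module detection, hubs, TF subnetwork."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from nitronet.network import (
    CoexprParams,
    detect_modules,
    module_enrichment,
    overlay_gene_list,
    pearson_adjacency,
    pick_soft_threshold,
    tf_target_subnetwork,
    threshold_and_hubs,
    topological_overlap,
)
from nitronet.synthetic import generate_module_expression, generate_tf_benchmark


def naive_to(a: np.ndarray) -> np.ndarray:
    """Double-loop evaluation of the printed TO formula (oracle)."""
    n = len(a)
    k = np.array([a[i].sum() - a[i, i] for i in range(n)])
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]])
        a = pearson_adjacency(expr, beta=1)
        assert a[0, 1] == pytest.approx(1.0)

    def test_beta_powers_hand_correlations(self, rng):
        expr = pd.DataFrame(rng.normal(size=(4, 30)))
        r = np.corrcoef(expr.to_numpy())
        a = pearson_adjacency(expr, beta=2)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(a[off], (np.abs(r) ** 2)[off])

    def test_damping_monotone_in_beta(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 50)))
        a1 = pearson_adjacency(expr, beta=2)
        a2 = pearson_adjacency(expr, beta=6)
        off = ~np.eye(10, dtype=bool)
        assert (a2[off] <= a1[off] + 1e-12).all()

    def test_zero_variance_gene_warned_and_zeroed(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.warns(UserWarning):
            a = pearson_adjacency(expr, beta=1)
        assert a[0, 1] == 0.0 and a[0, 0] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            pearson_adjacency(pd.DataFrame([[1.0, 2.0]]), beta=1)


class TestSoftThreshold:
    def test_mean_connectivity_strictly_decreases(self, rng):
        expr, _ = generate_module_expression(3, 25, 40, 0.6, n_background=30,
                                             seed=2)
        _, fit = pick_soft_threshold(expr, list(range(1, 9)))
        assert (np.diff(fit["mean_k"]) < 0).all()

    def test_choice_deterministic(self):
        expr, _ = generate_module_expression(3, 25, 40, 0.6, seed=3)
        b1, _ = pick_soft_threshold(expr)
        b2, _ = pick_soft_threshold(expr)
        assert b1 == b2

    def test_agrees_with_independent_reimplementation(self):
        # independent naive reimplementation of the fit-and-select rule
        expr, _ = generate_module_expression(4, 30, 50, 0.7, n_background=40,
                                             seed=4)
        powers = list(range(1, 11))
        chosen, _ = pick_soft_threshold(expr, powers, rsq_target=0.8)
        r = np.corrcoef(expr.to_numpy())
        signed_rsq = []
        for p in powers:
            a = np.abs(r) ** p
            np.fill_diagonal(a, 1.0)
            k = a.sum(axis=1) - 1
            k = k[k > 0]
            edges = np.linspace(k.min(), k.max(), 11)
            idx = np.clip(np.digitize(k, edges[1:-1]), 0, 9)
            xs, ys = [], []
            for b in range(10):
                if (idx == b).sum():
                    xs.append(np.log10(k[idx == b].mean()))
                    ys.append(np.log10((idx == b).sum() / k.size))
            slope, icpt = np.polyfit(xs, ys, 1)
            pred = slope * np.asarray(xs) + icpt
            rsq = 1 - ((np.asarray(ys) - pred) ** 2).sum() / (
                (np.asarray(ys) - np.mean(ys)) ** 2).sum()
            signed_rsq.append(-rsq if slope > 0 else rsq)
        reaching = [p for p, s in zip(powers, signed_rsq) if s >= 0.8]
        independent = reaching[0] if reaching else powers[int(np.argmax(signed_rsq))]
        assert abs(chosen - independent) <= 2


class TestTopologicalOverlap:
    def test_all_zero_adjacency(self):
        a = np.eye(5)
        to = topological_overlap(a * 0 + np.eye(5))
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(to[off], 0.0)
        assert np.allclose(np.diag(to), 1.0)

    def test_isolated_perfect_pair(self):
        a = np.eye(2)
        a[0, 1] = a[1, 0] = 1.0
        assert topological_overlap(a)[0, 1] == pytest.approx(1.0)

    def test_three_node_printed_formula(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        assert topological_overlap(a)[0, 1] == pytest.approx(0.5)

    def test_matches_double_loop_oracle(self, rng):
        a = rng.uniform(size=(50, 50))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        to = topological_overlap(a)
        assert np.abs(to - naive_to(a)).max() < 1e-12

    def test_range_zero_one(self, rng):
        for _ in range(5):
            a = rng.uniform(size=(30, 30))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 1.0)
            to = topological_overlap(a)
            assert to.min() >= -1e-12 and to.max() <= 1.0 + 1e-12

    def test_asymmetric_rejected(self, rng):
        a = rng.uniform(size=(4, 4))
        with pytest.raises(ValueError):
            topological_overlap(a)


class TestModuleDetection:
    def test_two_perfect_blocks(self):
        n = 35
        to = np.zeros((2 * n, 2 * n))
        to[:n, :n] = 0.9
        to[n:, n:] = 0.9
        np.fill_diagonal(to, 1.0)
        labels = detect_modules(to, CoexprParams(min_module_size=30))
        assert labels.nunique() == 2
        assert labels.iloc[:n].nunique() == 1 and labels.iloc[n:].nunique() == 1

    def test_identical_profiles_single_module(self):
        to = np.ones((40, 40))
        labels = detect_modules(to, CoexprParams(min_module_size=30))
        assert labels.nunique() == 1

    def test_fewer_genes_than_min_size_all_unassigned(self):
        to = np.eye(10)
        labels = detect_modules(to, CoexprParams(min_module_size=30))
        assert (labels == 0).all()

    def test_planted_module_recovery(self):
        expr, truth = generate_module_expression(5, 40, 60, 0.64, seed=0)
        a = pearson_adjacency(expr, beta=7)
        labels = detect_modules(topological_overlap(a), genes=expr.index)
        assert adjusted_rand_score(truth.to_numpy(), labels.to_numpy()) >= 0.9

    def test_gene_order_permutation_invariance(self, rng):
        expr, _ = generate_module_expression(3, 32, 50, 0.7, seed=5)
        a = pearson_adjacency(expr, beta=6)
        to = topological_overlap(a)
        labels = detect_modules(to, genes=expr.index)
        perm = rng.permutation(len(expr))
        labels_p = detect_modules(to[np.ix_(perm, perm)],
                                  genes=expr.index[perm])
        aligned = labels_p.reindex(expr.index)
        assert adjusted_rand_score(labels.to_numpy(), aligned.to_numpy()) == 1.0


class TestThresholdAndHubs:
    TO = np.array([
        [1.0, 0.5, 0.3, 0.05, 0.0],
        [0.5, 1.0, 0.2, 0.0, 0.0],
        [0.3, 0.2, 1.0, 0.15, 0.0],
        [0.05, 0.0, 0.15, 1.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 1.0],
    ])

    def modules(self):
        return pd.Series([1, 1, 1, 1, 1], index=list("abcde"), name="module")

    def test_manual_edge_enumeration(self):
        edges, degrees, hubs = threshold_and_hubs(self.TO, self.modules(), 0.10)
        got = {frozenset((a, b)) for a, b in zip(edges["gene_a"], edges["gene_b"])}
        assert got == {frozenset("ab"), frozenset("ac"), frozenset("bc"),
                       frozenset("cd")}
        assert degrees.to_dict() == {"a": 2, "b": 2, "c": 3, "d": 1, "e": 0}
        assert hubs.iloc[0]["gene"] == "c"

    def test_threshold_above_max_empty(self):
        edges, degrees, _ = threshold_and_hubs(self.TO, self.modules(), 0.99)
        assert edges.empty and (degrees == 0).all()

    def test_zero_threshold_complete_graph(self):
        edges, degrees, _ = threshold_and_hubs(self.TO, self.modules(), 0.0)
        assert len(edges) == 10 and (degrees == 4).all()

    def test_degree_ranking_invariant_to_subthreshold_edges(self):
        to2 = self.TO.copy()
        to2[3, 4] = to2[4, 3] = 0.05  # below threshold: must not matter
        _, _, hubs1 = threshold_and_hubs(self.TO, self.modules(), 0.10)
        _, _, hubs2 = threshold_and_hubs(to2, self.modules(), 0.10)
        assert list(hubs1["gene"]) == list(hubs2["gene"])


class TestOverlay:
    def labels(self):
        return pd.Series([1] * 10 + [2] * 10, index=[f"g{i}" for i in range(20)])

    def test_empty_list_all_zero(self):
        ov = overlay_gene_list(self.labels(), set())
        assert (ov["fraction"] == 0).all()

    def test_full_list_all_one(self):
        ov = overlay_gene_list(self.labels(), {f"g{i}" for i in range(20)})
        assert (ov["fraction"] == 1.0).all()

    def test_concentrated_flags_rank_first(self):
        ov = overlay_gene_list(self.labels(), {f"g{i}" for i in range(8)})
        assert ov.iloc[0]["module"] == 1 and ov.iloc[0]["rank"] == 1


class TestTfSubnetwork:
    def test_planted_structure_recovered(self):
        bench = generate_tf_benchmark(seed=0)
        a = pearson_adjacency(bench.expression, beta=7)
        to = topological_overlap(a)
        edges, ranking = tf_target_subnetwork(
            to, bench.expression.index, bench.tf_motifs, bench.motif_table)
        pred = set(zip(edges["tf"], edges["target"]))
        tp = len(pred & bench.true_edges)
        assert tp / len(pred) >= 0.8
        assert tp / len(bench.true_edges) >= 0.8
        assert set(ranking["tf"]) <= set(bench.tf_motifs)

    def test_motif_nowhere_no_edges(self):
        bench = generate_tf_benchmark(seed=1)
        motifs = bench.motif_table.copy()
        motifs.loc[:, :] = False
        a = pearson_adjacency(bench.expression, beta=7)
        edges, _ = tf_target_subnetwork(
            topological_overlap(a), bench.expression.index, bench.tf_motifs,
            motifs)
        assert edges.empty

    def test_threshold_above_max_empty(self):
        bench = generate_tf_benchmark(seed=2)
        a = pearson_adjacency(bench.expression, beta=7)
        to = topological_overlap(a)
        np.fill_diagonal(to, 1.0)
        edges, _ = tf_target_subnetwork(
            to, bench.expression.index, bench.tf_motifs, bench.motif_table,
            CoexprParams(edge_threshold=1.0))
        assert edges.empty

    def test_absent_tf_skipped_with_warning(self):
        bench = generate_tf_benchmark(seed=3)
        a = pearson_adjacency(bench.expression, beta=7)
        tf_motifs = dict(bench.tf_motifs)
        tf_motifs["not_a_gene"] = ["M_x"]
        with pytest.warns(UserWarning):
            tf_target_subnetwork(topological_overlap(a),
                                 bench.expression.index, tf_motifs,
                                 bench.motif_table)


class TestModuleEnrichment:
    def test_planted_module_recovers_its_term(self):
        from nitronet.ontology import GoResources
        genes = [f"g{i}" for i in range(120)]
        dag = pd.DataFrame([("T1", "root"), ("T2", "root")],
                           columns=["child", "parent"])
        ann = {g: {"T1"} for g in genes[:40]}
        ann.update({g: {"T2"} for g in genes[40:]})
        res = GoResources.from_tables(dag, ann)
        module_of = pd.Series([1] * 40 + [0] * 80, index=genes)
        rows = module_enrichment(module_of, res)
        top = rows.sort_values("p").iloc[0]
        assert top["term"] == "T1" and top["enriched"]

    def test_no_modules_empty_result(self):
        from nitronet.ontology import GoResources
        dag = pd.DataFrame([("T1", "root")], columns=["child", "parent"])
        res = GoResources.from_tables(dag, {"g0": {"T1"}})
        rows = module_enrichment(pd.Series([0], index=["g0"]), res)
        assert rows.empty
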