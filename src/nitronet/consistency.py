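"""Cross-experiment consistency statistics and their controls.

Given per-experiment differential-expression calls and per-experiment
enriched GO terms, this module quantifies the central observation of the
meta-analysis: gene identities vary between experiments while biological
functions recur.  It provides

* the per-gene consistency ranking (how many experiments regulate a gene,
  split by direction),
* overlap curves — the mean percentage of shared genes vs. shared enriched
  terms over all m-experiment combinations,
* the three control analyses (level distributions of shared vs. all enriched
  terms, annotation counts of random gene lists, gene overlap inside shared
  terms), and
* the protein-similarity permutation test asking whether genes contributed
  to a shared term by different experiments are more similar in protein
  sequence than random gene pairs annotated to that term — the signature of
  family-level functional degeneracy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd


class SimilarityTable:
    """Symmetric gene-pair similarity lookup with filter semantics.

    Pairs absent from the table score 0 (they failed the E-value filter of
    the upstream alignment); self-pairs score 1.
    """

    def __init__(self, table: pd.DataFrame):
        self._scores: dict[frozenset, float] = {}
        for a, b, s in zip(table["gene_a"], table["gene_b"], table["score"]):
            if a != b:
                self._scores[frozenset((a, b))] = float(s)

    def score(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._scores.get(frozenset((a, b)), 0.0)

    def __len__(self) -> int:
        return len(self._scores)


def consistency_ranking(direction_sets: dict[str, dict[str, set[str]]]) -> pd.DataFrame:
    """Rank genes by the number of experiments in which they are regulated.

    ``direction_sets`` maps experiment -> {'up': genes, 'down': genes} with a
    gene counted at most once per experiment.  Output columns: gene, total,
    up, down; sorted by total desc, up desc, gene id; genes never called are
    omitted.
    """
    up_counts: dict[str, int] = {}
    down_counts: dict[str, int] = {}
    for sets in direction_sets.values():
        for g in sets.get("up", ()):
            up_counts[g] = up_counts.get(g, 0) + 1
        for g in sets.get("down", ()):
            down_counts[g] = down_counts.get(g, 0) + 1
    genes = sorted(set(up_counts) | set(down_counts))
    df = pd.DataFrame({
        "gene": genes,
        "up": [up_counts.get(g, 0) for g in genes],
        "down": [down_counts.get(g, 0) for g in genes],
    })
    df["total"] = df["up"] + df["down"]
    df = df[df["total"] > 0]
    df = df.sort_values(["total", "up", "gene"], ascending=[False, False, True],
                        kind="stable").reset_index(drop=True)
    return df[["gene", "total", "up", "down"]]


def shared_fraction(sets: list[set], metric: str = "jaccard") -> float:
    """Percentage of elements shared by all m sets.

    ``jaccard``: 100 * |intersection| / |union| (0 if the union is empty);
    ``intersection_over_mean``: 100 * |intersection| / mean set size — kept
    as a sensitivity alternative since "shared percentage" admits either
    normalization.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    inter = set.intersection(*map(set, sets))
    if metric == "jaccard":
        union = set.union(*map(set, sets))
        return 100.0 * len(inter) / len(union) if union else 0.0
    if metric == "intersection_over_mean":
        mean_size = np.mean([len(s) for s in sets])
        return 100.0 * len(inter) / mean_size if mean_size else 0.0
    raise ValueError(f"unknown overlap metric {metric!r}")


def overlap_curves(
    de_gene_sets: dict[str, set[str]],
    enriched_term_sets: dict[str, set[str]],
    max_combos: int = 10_000,
    seed: int = 0,
    metric: str = "jaccard",
) -> pd.DataFrame:
    """Mean shared percentage of genes and of enriched terms per tuple size m.

    For every m in 2..E the mean is over all C(E, m) experiment combinations
    when that count is at most ``max_combos``, otherwise over ``max_combos``
    uniformly sampled combinations (``sampled`` flag set).  Gene and term
    means use identical combinations, so the curves are directly comparable.
    """
    exps = sorted(de_gene_sets)
    if set(enriched_term_sets) != set(de_gene_sets):
        raise ValueError("gene and term sets must cover the same experiments")
    E = len(exps)
    if E < 2:
        raise ValueError("need at least two experiments")
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(2, E + 1):
        total = comb(E, m)
        if total <= max_combos:
            combos = list(itertools.combinations(exps, m))
            sampled = False
        else:
            combos = [tuple(rng.choice(exps, size=m, replace=False))
                      for _ in range(max_combos)]
            sampled = True
        g_vals = [shared_fraction([de_gene_sets[e] for e in c], metric) for c in combos]
        t_vals = [shared_fraction([enriched_term_sets[e] for e in c], metric) for c in combos]
        rows.append((m, float(np.mean(g_vals)), float(np.mean(t_vals)),
                     len(combos), sampled))
    return pd.DataFrame(rows, columns=["m", "gene_overlap_pct", "go_overlap_pct",
                                       "n_combinations_evaluated", "sampled"])


def pairwise_shared_terms(
    enriched_term_sets: dict[str, set[str]],
) -> dict[tuple[str, str], set[str]]:
    """Enriched terms shared by each experiment pair."""
    return {
        (a, b): enriched_term_sets[a] & enriched_term_sets[b]
        for a, b in itertools.combinations(sorted(enriched_term_sets), 2)
    }


@dataclass
class LevelControl:
    """Level histograms of all vs. pairwise-shared enriched terms."""

    total_hist: pd.Series  # level -> probability (over experiment-term occurrences)
    shared_hist: pd.Series  # level -> probability (over pair-term occurrences)
    tv_distance: float  # total-variation distance; NaN when shared is empty
    flagged_empty: bool


def level_distribution_control(
    enriched_terms_per_experiment: dict[str, set[str]],
    shared_terms_per_pair: dict[tuple[str, str], set[str]],
    levels: dict[str, int],
) -> LevelControl:
    """Compare GO-level distributions of all enriched vs. shared enriched terms.

    Similar distributions indicate shared terms are not an artifact of very
    general (shallow) categories.
    """
    total = [levels[t] for terms in enriched_terms_per_experiment.values() for t in terms
             if t in levels]
    shared = [levels[t] for terms in shared_terms_per_pair.values() for t in terms
              if t in levels]
    all_levels = sorted(set(total) | set(shared))
    t_hist = pd.Series(
        [total.count(lv) / len(total) if total else 0.0 for lv in all_levels],
        index=all_levels, name="total",
    )
    if not shared:
        return LevelControl(t_hist, pd.Series(dtype=float, name="shared"),
                            float("nan"), True)
    s_hist = pd.Series([shared.count(lv) / len(shared) for lv in all_levels],
                       index=all_levels, name="shared")
    tv = 0.5 * float(np.abs(t_hist.to_numpy() - s_hist.to_numpy()).sum())
    return LevelControl(t_hist, s_hist, tv, False)


@dataclass
class RandomListControl:
    """Annotation counts of random gene lists vs. the observed DE list."""

    mean: float
    sd: float
    counts: np.ndarray
    observed: int | None
    observed_quantile: float | None


def random_list_annotation_control(
    universe: list[str] | set[str],
    annotations: dict[str, set[str]],
    list_size: int,
    n_iter: int = 1000,
    seed: int = 0,
    observed_genes: set[str] | None = None,
) -> RandomListControl:
    """Distinct-GO-term counts of random gene lists of the DE-list size.

    Each of ``n_iter`` draws samples ``list_size`` genes uniformly without
    replacement from the universe and counts the distinct terms annotated to
    them.  If ``observed_genes`` is given, its count and empirical quantile
    within the null distribution are reported.
    """
    universe = sorted(universe)
    if list_size > len(universe):
        raise ValueError("list_size exceeds the universe")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_iter, dtype=int)
    for i in range(n_iter):
        drawn = rng.choice(universe, size=list_size, replace=False)
        terms: set[str] = set()
        for g in drawn:
            terms |= annotations.get(g, set())
        counts[i] = len(terms)
    observed = None
    quantile = None
    if observed_genes is not None:
        obs_terms: set[str] = set()
        for g in observed_genes:
            obs_terms |= annotations.get(g, set())
        observed = len(obs_terms)
        quantile = float(np.mean(counts < observed))
    return RandomListControl(float(counts.mean()), float(counts.std(ddof=1)) if n_iter > 1 else 0.0,
                             counts, observed, quantile)


@dataclass
class SharedTermGeneOverlap:
    """Gene overlap inside shared enriched terms, per (pair, term)."""

    grand_mean_pct: float  # NaN when no shared terms exist
    table: pd.DataFrame
    flagged_empty: bool


def shared_term_gene_overlap(
    shared_terms_per_pair: dict[tuple[str, str], set[str]],
    de_gene_sets: dict[str, set[str]],
    term_to_genes: dict[str, set[str]],
    metric: str = "jaccard",
) -> SharedTermGeneOverlap:
    """How many of the *same* genes drive a term shared by two experiments.

    For each experiment pair and shared term, the shared percentage of the
    two experiments' DE genes annotated to that term; low values mean the
    shared function is realized through different genes.
    """
    rows = []
    for (a, b), terms in sorted(shared_terms_per_pair.items()):
        for t in sorted(terms):
            ann = term_to_genes.get(t, set())
            ga = de_gene_sets[a] & ann
            gb = de_gene_sets[b] & ann
            pct = shared_fraction([ga, gb], metric)
            rows.append((a, b, t, len(ga), len(gb), pct))
    table = pd.DataFrame(rows, columns=["exp_a", "exp_b", "term", "n_genes_a",
                                        "n_genes_b", "overlap_pct"])
    if table.empty:
        return SharedTermGeneOverlap(float("nan"), table, True)
    return SharedTermGeneOverlap(float(table["overlap_pct"].mean()), table, False)


@dataclass
class SimilarityTestResult:
    term: str
    n_cross_pairs: int
    observed_stat: float
    null_quantile: float
    significant: bool
    skipped: bool
    skip_reason: str | None = None


def cross_experiment_similarity_test(
    term: str,
    contributors: dict[str, set[str]],
    similarity: SimilarityTable,
    annotated: set[str],
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = 0.05,
    statistic: str = "mean",
    sim_threshold: float = 0.5,
) -> SimilarityTestResult:
    """Are cross-experiment contributors to a shared term unusually similar?

    Observed statistic over all distinct cross-experiment gene pairs (one
    gene per experiment, different genes; absent pairs score 0):
    ``mean`` similarity, or the ``count`` of pairs at or above
    ``sim_threshold``.  The null draws the same number of pairs uniformly
    without replacement from all distinct pairs of genes annotated to the
    term; significance requires the observed statistic to exceed the
    (1 - alpha) null quantile.  Terms with fewer than two annotated genes or
    fewer than two cross-experiment pairs are skipped.
    """
    annotated = sorted(annotated)
    if len(annotated) < 2:
        return SimilarityTestResult(term, 0, float("nan"), float("nan"),
                                    False, True, "fewer than 2 annotated genes")
    cross: set[frozenset] = set()
    for (ea, ga), (eb, gb) in itertools.combinations(
            sorted(contributors.items()), 2):
        for x in ga:
            for y in gb:
                if x != y:
                    cross.add(frozenset((x, y)))
    n_obs = len(cross)
    if n_obs < 2:
        return SimilarityTestResult(term, n_obs, float("nan"), float("nan"),
                                    False, True, "fewer than 2 cross-experiment pairs")

    all_pairs = list(itertools.combinations(annotated, 2))
    scores = np.array([similarity.score(a, b) for a, b in all_pairs])
    n_all = len(all_pairs)
    n_draw = min(n_obs, n_all)

    def stat(values: np.ndarray) -> float:
        if statistic == "mean":
            return float(values.mean())
        if statistic == "count":
            return float((values >= sim_threshold).sum())
        raise ValueError(f"unknown statistic {statistic!r}")

    # fixed pair order: summation must not depend on set-iteration order
    cross_sorted = sorted(tuple(sorted(p)) for p in cross)
    observed = stat(np.array([similarity.score(a, b) for a, b in cross_sorted]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n_all, size=n_draw, replace=False)
        null[i] = stat(scores[idx])
    threshold_val = float(np.quantile(null, 1.0 - alpha))
    significant = bool(observed > threshold_val)
    null_quantile = float(np.mean(null < observed))
    return SimilarityTestResult(term, n_obs, observed, null_quantile,
                                significant, False, None)


def similarity_tests_for_shared_terms(
    shared_terms_per_pair: dict[tuple[str, str], set[str]],
    de_gene_sets: dict[str, set[str]],
    term_to_genes: dict[str, set[str]],
    similarity: SimilarityTable,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Run the similarity test once per term shared by >= 2 experiments.

    A term's contributors are, per experiment, its annotated DE genes across
    every pair in which the term is shared.  Returns one row per tested
    term; the fraction of non-skipped terms with ``significant`` True is the
    study-level verdict.
    """
    term_contrib: dict[str, dict[str, set[str]]] = {}
    for (a, b), terms in shared_terms_per_pair.items():
        for t in terms:
            d = term_contrib.setdefault(t, {})
            ann = term_to_genes.get(t, set())
            d.setdefault(a, set()).update(de_gene_sets[a] & ann)
            d.setdefault(b, set()).update(de_gene_sets[b] & ann)
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(max(len(term_contrib), 1)))
    rows = []
    for t in sorted(term_contrib):
        res = cross_experiment_similarity_test(
            t, term_contrib[t], similarity, term_to_genes.get(t, set()),
            n_perm=n_perm, seed=next(children), alpha=alpha, statistic=statistic,
        )
        rows.append((res.term, res.n_cross_pairs, res.observed_stat,
                     res.null_quantile, res.significant, res.skipped, res.skip_reason))
    return pd.DataFrame(rows, columns=["term", "n_cross_pairs", "observed_stat",
                                       "null_quantile", "significant", "skipped",
                                       "skip_reason"])


def evaluate_simulated_terms(
    terms,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "mean",
) -> float:
    """Fraction of simulated shared terms called significant (skips excluded)."""
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(terms)))
    n_sig = 0
    n_tested = 0
    for t in terms:
        res = cross_experiment_similarity_test(
            t.term, t.contributors, SimilarityTable(t.similarity), t.annotated,
            n_perm=n_perm, seed=next(children), alpha=alpha, statistic=statistic,
        )
        if not res.skipped:
            n_tested += 1
            n_sig += int(res.significant)
    return n_sig / n_tested if n_tested else float("nan")
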