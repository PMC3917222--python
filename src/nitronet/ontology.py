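"""GO DAG handling and gene-set over-representation testing.

The ontology is an is_a-style DAG given as a child -> parent edge list with a
single root.  A term's *level* is the number of edges on the shortest path to
the root.  Enrichment of a gene set against a universe uses the one-sided
Fisher (hypergeometric upper-tail) test with Benjamini-Yekutieli FDR control,
and results can be restricted to a band of levels (the analysis convention is
levels 7 and 8, where terms are specific enough to name concrete functions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


class InvalidDagError(ValueError):
    pass


def _dag_from_edges(edges: pd.DataFrame) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_edges_from(zip(edges["child"], edges["parent"]))
    for col in ("child", "parent"):
        g.add_nodes_from(edges[col])
    return g


def compute_levels(dag: pd.DataFrame | nx.DiGraph) -> dict[str, int]:
    """Shortest-path level of every term (root = 0).

    ``dag`` is a child->parent edge list (DataFrame with columns ``child``,
    ``parent``) or the equivalent DiGraph.  Raises :class:`InvalidDagError`
    on cycles or if the DAG does not have exactly one root.
    """
    g = dag if isinstance(dag, nx.DiGraph) else _dag_from_edges(dag)
    if not nx.is_directed_acyclic_graph(g):
        raise InvalidDagError("cycle detected in ontology edges")
    roots = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(roots) != 1:
        raise InvalidDagError(f"ontology must have exactly one root, found {len(roots)}")
    root = roots[0]
    # BFS from the root along reversed (parent -> child) edges.
    levels = nx.single_source_shortest_path_length(g.reverse(copy=False), root)
    if len(levels) != g.number_of_nodes():
        raise InvalidDagError("some terms cannot reach the root")
    return dict(levels)


def ancestors_map(dag: pd.DataFrame | nx.DiGraph) -> dict[str, set[str]]:
    """Term -> set of all its ancestors (transitive parents, root included)."""
    g = dag if isinstance(dag, nx.DiGraph) else _dag_from_edges(dag)
    return {t: set(nx.descendants(g, t)) for t in g.nodes}


def propagate_annotations(
    annotations: dict[str, set[str]],
    dag: pd.DataFrame | nx.DiGraph,
) -> dict[str, set[str]]:
    """Close gene -> term annotations under ancestors (true-path rule).

    Idempotent.  Terms absent from the DAG are passed through with a warning.
    """
    g = dag if isinstance(dag, nx.DiGraph) else _dag_from_edges(dag)
    anc = ancestors_map(g)
    known = set(g.nodes)
    missing: set[str] = set()
    out: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        closed = set(terms)
        for t in terms:
            if t in known:
                closed |= anc[t]
            else:
                missing.add(t)
        out[gene] = closed
    if missing:
        warnings.warn(
            f"{len(missing)} annotated term(s) absent from the DAG were passed through",
            stacklevel=2,
        )
    return out


@dataclass
class GoResources:
    """Ontology DAG, term levels and (optionally propagated) annotations."""

    dag: nx.DiGraph
    levels: dict[str, int]
    annotations: dict[str, set[str]]  # gene -> terms
    propagated: bool = True
    term_to_genes: dict[str, set[str]] = field(default_factory=dict)

    @classmethod
    def from_tables(
        cls,
        dag_edges: pd.DataFrame,
        annotations: dict[str, set[str]],
        propagate: bool = True,
    ) -> "GoResources":
        g = _dag_from_edges(dag_edges)
        levels = compute_levels(g)
        ann = propagate_annotations(annotations, g) if propagate else {
            gene: set(terms) for gene, terms in annotations.items()
        }
        t2g: dict[str, set[str]] = {}
        for gene, terms in ann.items():
            for t in terms:
                t2g.setdefault(t, set()).add(gene)
        return cls(dag=g, levels=levels, annotations=ann, propagated=propagate,
                   term_to_genes=t2g)

    @property
    def root(self) -> str:
        return next(n for n, lv in self.levels.items() if lv == 0)

    def genes_of(self, term: str) -> set[str]:
        return self.term_to_genes.get(term, set())

    def terms_of(self, gene: str) -> set[str]:
        return self.annotations.get(gene, set())


def by_adjust(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values.

    The BY procedure multiplies the Benjamini-Hochberg values by the harmonic
    correction c(m) = sum_{i=1..m} 1/i, which keeps FDR control under
    arbitrary dependence among the tests (GO terms are strongly dependent
    through the DAG).  Output is monotone and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def fisher_pvalue(in_set_annotated: int, in_set_total: int,
                  universe_annotated: int, universe_total: int) -> float:
    """One-sided over-representation p for a single 2x2 table.

    Hypergeometric upper tail: probability of drawing at least
    ``in_set_annotated`` annotated genes in ``in_set_total`` draws from a
    universe of ``universe_total`` with ``universe_annotated`` annotated.
    """
    return float(hypergeom.sf(in_set_annotated - 1, universe_total,
                              universe_annotated, in_set_total))


def fisher_enrichment(
    gene_set: set[str],
    universe: set[str],
    resources: GoResources,
    alpha: float = 0.05,
    min_universe_annotated: int = 1,
) -> pd.DataFrame:
    """One-sided (over-representation) Fisher test for every annotated term.

    Tests, per term, the 2x2 table (in set & annotated / in set / annotated
    in universe / universe); the one-sided p-value is the hypergeometric
    upper tail.  Terms annotating no universe gene are omitted.  ``p_adj`` is
    Benjamini-Yekutieli across all tested terms; ``enriched`` is
    ``p_adj < alpha``.
    """
    gene_set = set(gene_set)
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")

    N, n = len(universe), len(gene_set)
    rows = []
    for term, genes in sorted(resources.term_to_genes.items()):
        K = len(genes & universe)
        if K < min_universe_annotated:
            continue
        k = len(genes & gene_set)
        rows.append((term, resources.levels.get(term, -1), k, n, K, N))
    if not rows:
        return pd.DataFrame(
            columns=["term", "level", "in_set_annotated", "in_set_total",
                     "universe_annotated", "universe_total", "p", "p_adj", "enriched"]
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "level", "in_set_annotated", "in_set_total",
                 "universe_annotated", "universe_total"],
    )
    df["p"] = hypergeom.sf(
        df["in_set_annotated"] - 1, df["universe_total"],
        df["universe_annotated"], df["in_set_total"],
    )
    df["p_adj"] = by_adjust(df["p"].to_numpy())
    df["enriched"] = df["p_adj"] < alpha
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


def filter_by_level(
    rows: pd.DataFrame,
    levels: dict[str, int] | None = None,
    allowed: set[int] = frozenset({7, 8}),
) -> pd.DataFrame:
    """Restrict enrichment rows to terms at the allowed ontology levels.

    If ``levels`` is None the ``level`` column of ``rows`` is used.  Order is
    preserved; this is a pure restriction.
    """
    if rows.empty:
        return rows.copy()
    if levels is None:
        lv = rows["level"]
    else:
        lv = rows["term"].map(levels)
    return rows[lv.isin(list(allowed))].copy()
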