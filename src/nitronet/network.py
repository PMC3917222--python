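"""Weighted gene coexpression network with topological overlap.

The adjacency is the unsigned soft-thresholded Pearson correlation,
``a_ij = |r_ij|^beta``; the soft power is chosen so the degree distribution
approximates scale-free topology.  Pairwise interconnectedness is measured
by the topological overlap

    TO_ij = (sum_{u != i,j} a_iu * a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with connectivity ``k_i = sum_{u != i} a_iu``; TO lies in [0, 1] and equals
1 on the diagonal.  Modules are branches of the average-linkage dendrogram
of ``1 - TO``, cut adaptively (tree-variant dynamic cut); hubs are the
highest-degree genes of each module on the TO-thresholded graph, and a
TF -> target subnetwork combines TO neighborhoods with promoter-motif
over-representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests


@dataclass
class CoexprParams:
    """Network construction parameters."""

    beta: int = 7
    rsq_target: float = 0.8
    edge_threshold: float = 0.10
    min_module_size: int = 30
    cut_height_quantile: float = 0.99

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        for name in ("rsq_target", "edge_threshold", "cut_height_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class NetworkState:
    """Adjacency, TO matrix and downstream assignments for one gene set."""

    genes: pd.Index
    adjacency: np.ndarray
    to: np.ndarray
    module_of: pd.Series | None = None
    degrees: pd.Series | None = None
    params: CoexprParams = field(default_factory=CoexprParams)

    @property
    def connectivity(self) -> pd.Series:
        return pd.Series(self.adjacency.sum(axis=1) - 1.0, index=self.genes, name="k")


def pearson_adjacency(expression: pd.DataFrame, beta: int = 7) -> np.ndarray:
    """Unsigned soft-thresholded adjacency ``|r|^beta`` with unit diagonal.

    ``expression`` is genes x samples.  Zero-variance genes get zero
    correlation to everything (with a warning) rather than NaNs.
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    arr = expression.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        warnings.warn(f"{flat.size} zero-variance gene(s); correlations set to 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    r[~np.isfinite(r)] = 0.0
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed R^2 of the log10 degree-distribution fit and its slope.

    Connectivities are discretized into equal-width bins; log10 frequency is
    regressed on log10 mean connectivity per (non-empty) bin.  The R^2 is
    negated when the slope is positive, so only decaying distributions score
    as scale-free.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    fitted = slope * np.asarray(xs) + intercept
    ss_res = float(((np.asarray(ys) - fitted) ** 2).sum())
    ss_tot = float(((np.asarray(ys) - np.mean(ys)) ** 2).sum())
    rsq = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return (-rsq if slope > 0 else rsq), float(slope)


def pick_soft_threshold(
    expression: pd.DataFrame,
    candidate_powers: list[int] | None = None,
    rsq_target: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft power: smallest with signed scale-free R^2 >= target.

    Falls back to the power with the highest signed R^2 when no candidate
    reaches the target.  Returns the chosen power and the per-power fit
    table (signed R^2, slope, mean and median connectivity).
    """
    if candidate_powers is None:
        candidate_powers = list(range(1, 13))
    if len(candidate_powers) < 2:
        raise ValueError("need at least two candidate powers")
    rows = []
    for p in candidate_powers:
        a = pearson_adjacency(expression, beta=p)
        k = a.sum(axis=1) - 1.0
        rsq, slope = _scale_free_fit(k)
        rows.append((p, rsq, slope, float(k.mean()), float(np.median(k))))
    table = pd.DataFrame(rows, columns=["power", "rsq_signed", "slope",
                                        "mean_k", "median_k"])
    ok = table[table["rsq_signed"] >= rsq_target]
    chosen = int(ok["power"].iloc[0]) if len(ok) else int(
        table.loc[table["rsq_signed"].idxmax(), "power"])
    return chosen, table


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0, 1].

    Matrix form of the pairwise formula: the shared-neighbor sum is
    ``(A @ A)_ij - a_ii a_ij - a_ij a_jj``; connectivity excludes the
    diagonal.  The diagonal of the result is defined as 1.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    diag = np.diag(a).copy()
    shared = a @ a - np.outer(diag, np.ones(len(a))) * a - a * np.outer(np.ones(len(a)), diag)
    k = a.sum(axis=1) - diag
    min_k = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        to = (shared + a) / (min_k + 1.0 - a)
    to[~np.isfinite(to)] = 0.0
    np.fill_diagonal(to, 1.0)
    return to


def _cut_once(link: np.ndarray, quantile: float) -> np.ndarray:
    heights = link[:, 2]
    h = float(np.quantile(heights, quantile))
    # cut strictly below the tallest merges at or above h
    return fcluster(link, t=h, criterion="distance")


def detect_modules(
    to: np.ndarray,
    params: CoexprParams | None = None,
    genes: pd.Index | None = None,
) -> pd.Series:
    """Branch-cut the average-linkage dendrogram of 1 - TO into modules.

    Tree-variant adaptive cut: a static cut at the ``cut_height_quantile``
    of merge heights seeds the branches, then each branch is re-cut.  A cut
    that yields two or more children of size >= ``min_module_size`` is a
    real split and each child is processed in turn; a cut that yields one
    big child plus undersized offcuts is treated as noise chaining — the
    offcuts are peeled off (label 0 later) and the big branch is re-cut.
    Branches that cannot split further become modules; undersized leftovers
    get label 0.  Module labels are renumbered by decreasing size.
    """
    params = params or CoexprParams()
    n = to.shape[0]
    if genes is None:
        genes = pd.RangeIndex(n)
    if n < params.min_module_size:
        return pd.Series(0, index=genes, name="module")

    def split(indices: np.ndarray) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        while True:
            if indices.size < 2 * params.min_module_size:
                out.append(indices)
                return out
            sub = 1.0 - to[np.ix_(indices, indices)]
            np.fill_diagonal(sub, 0.0)
            sub = (sub + sub.T) / 2.0
            link = linkage(squareform(sub, checks=False), method="average")
            labels = _cut_once(link, params.cut_height_quantile)
            groups = [indices[labels == lb] for lb in np.unique(labels)]
            big = [g for g in groups if g.size >= params.min_module_size]
            if len(groups) == 1 or not big:
                out.append(indices)
                return out
            if len(big) == 1:  # noise chaining: peel offcuts, descend
                out.extend(g for g in groups if g.size < params.min_module_size)
                indices = big[0]
                continue
            for g in groups:
                if g.size >= params.min_module_size:
                    out.extend(split(g))
                else:
                    out.append(g)
            return out

    branches = split(np.arange(n))
    modules = [b for b in branches if b.size >= params.min_module_size]
    modules.sort(key=lambda b: (-b.size, b[0]))
    labels = np.zeros(n, dtype=int)
    for i, b in enumerate(modules, start=1):
        labels[b] = i
    return pd.Series(labels, index=genes, name="module")


def threshold_and_hubs(
    to: np.ndarray,
    module_of: pd.Series,
    edge_threshold: float = 0.10,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Thresholded edge list, degrees, and per-module hub ranking.

    Edges are undirected pairs with TO >= threshold; degree counts incident
    edges.  Hubs are ranked within each module by degree, ties broken by
    summed incident TO then gene id — a deterministic ordering.
    """
    genes = module_of.index
    n = len(genes)
    iu = np.triu_indices(n, k=1)
    mask = to[iu] >= edge_threshold
    ga = genes[iu[0][mask]]
    gb = genes[iu[1][mask]]
    edges = pd.DataFrame({"gene_a": ga, "gene_b": gb, "to": to[iu][mask]})

    adj_mask = (to >= edge_threshold)
    np.fill_diagonal(adj_mask, False)
    degrees = pd.Series(adj_mask.sum(axis=1), index=genes, name="degree")
    to_sum = pd.Series(np.where(adj_mask, to, 0.0).sum(axis=1), index=genes,
                       name="to_sum")

    hub = pd.DataFrame({"gene": genes, "module": module_of.to_numpy(),
                        "degree": degrees.to_numpy(), "to_sum": to_sum.to_numpy()})
    hub = hub[hub["module"] > 0]
    hub = hub.sort_values(["module", "degree", "to_sum", "gene"],
                          ascending=[True, False, False, True], kind="stable")
    hub["rank_in_module"] = hub.groupby("module").cumcount() + 1
    return edges, degrees, hub.reset_index(drop=True)


def module_enrichment(
    module_of: pd.Series,
    resources,
    universe: set[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """GO over-representation of every module against the network universe.

    Label 0 (unassigned) is excluded.  Returns the concatenated enrichment
    tables with a leading ``module`` column.
    """
    from .ontology import fisher_enrichment

    if universe is None:
        universe = set(module_of.index)
    frames = []
    for m in sorted(set(module_of.unique()) - {0}):
        members = set(module_of.index[module_of == m])
        rows = fisher_enrichment(members & universe, universe, resources, alpha=alpha)
        rows.insert(0, "module", m)
        frames.append(rows)
    if not frames:
        return pd.DataFrame(columns=["module", "term", "level", "in_set_annotated",
                                     "in_set_total", "universe_annotated",
                                     "universe_total", "p", "p_adj", "enriched"])
    return pd.concat(frames, ignore_index=True)


def overlay_gene_list(module_of: pd.Series, flagged_genes: set[str]) -> pd.DataFrame:
    """Per-module fraction of flagged genes (e.g. direct-nitrate-signal).

    Modules are ranked by flagged fraction, descending; label 0 excluded.
    """
    rows = []
    for m in sorted(set(module_of.unique()) - {0}):
        members = module_of.index[module_of == m]
        n_flag = sum(g in flagged_genes for g in members)
        rows.append((m, len(members), n_flag,
                     n_flag / len(members) if len(members) else 0.0))
    df = pd.DataFrame(rows, columns=["module", "n_genes", "n_flagged", "fraction"])
    df = df.sort_values(["fraction", "module"], ascending=[False, True],
                        kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def tf_target_subnetwork(
    to: np.ndarray,
    genes: pd.Index,
    tf_motifs: dict[str, list[str]],
    motif_table: pd.DataFrame,
    params: CoexprParams | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Predict TF -> target edges from TO neighborhoods plus motif enrichment.

    For each TF: its neighborhood is every gene with TO >= edge_threshold;
    each of its motifs is tested (one-sided Fisher) for over-representation
    among neighbors vs. non-neighbors, BH-corrected across the TF's motifs.
    Edges go to neighbors that carry a significantly over-represented motif.
    TFs absent from the network are skipped with a warning.

    Returns (edge table, TF out-degree ranking).
    """
    params = params or CoexprParams()
    pos = {g: i for i, g in enumerate(genes)}
    edge_rows = []
    for tf in sorted(tf_motifs):
        if tf not in pos:
            warnings.warn(f"TF {tf} absent from the network; skipped", stacklevel=2)
            continue
        i = pos[tf]
        neigh_mask = (to[i] >= params.edge_threshold)
        neigh_mask[i] = False
        neighbors = [g for g in genes if neigh_mask[pos[g]]]
        if not neighbors:
            continue
        motifs = tf_motifs[tf]
        pvals = []
        for motif in motifs:
            if motif not in motif_table.columns:
                pvals.append(1.0)
                continue
            present = motif_table[motif].reindex(genes).fillna(False).astype(bool)
            in_n = present.to_numpy()[[pos[g] for g in neighbors]].sum()
            out_total = len(genes) - 1 - len(neighbors)
            out_n = int(present.sum()) - in_n - int(present.get(tf, False))
            table = [[in_n, len(neighbors) - in_n],
                     [out_n, out_total - out_n]]
            pvals.append(fisher_exact(table, alternative="greater")[1])
        p_adj = multipletests(pvals, method="fdr_bh")[1] if pvals else []
        sig_motifs = {m: q for m, q in zip(motifs, p_adj) if q < alpha}
        if not sig_motifs:
            continue
        for g in neighbors:
            carried = [m for m in sig_motifs
                       if m in motif_table.columns and bool(motif_table.loc[g, m])]
            if carried:
                edge_rows.append((tf, g, float(to[i, pos[g]]),
                                  min(sig_motifs[m] for m in carried)))
    edges = pd.DataFrame(edge_rows, columns=["tf", "target", "to_score", "motif_p_adj"])
    ranking = (edges.groupby("tf").size().rename("out_degree")
               .sort_values(ascending=False).reset_index()
               if len(edges) else pd.DataFrame(columns=["tf", "out_degree"]))
    return edges, ranking
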