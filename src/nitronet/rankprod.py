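"""Rank Products differential expression with permutation-based PFP.

The Rank Products statistic (Breitling-style) is the geometric mean of a
gene's fold-change ranks across all treatment x control comparisons of an
experiment.  It is rank-based, hence robust for the small replicate numbers
typical of public microarray series, and is attached here to a
percentage-of-false-prediction (PFP) estimate obtained by permuting the
per-comparison rank vectors.

Up- and down-regulation are analysed separately; a gene's experiment-level
call is "significant in either direction".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

TREATMENT = "treatment"
CONTROL = "control"


@dataclass
class Experiment:
    """One contrast: a log2 expression matrix plus a treatment/control design.

    Parameters
    ----------
    id:
        Experiment identifier (Table-1-style numbering or any string).
    expression:
        genes x samples DataFrame of log2 intensities.
    design:
        Series mapping sample name -> ``"treatment"`` or ``"control"``.
    """

    id: str
    expression: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        missing = [s for s in self.expression.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"experiment {self.id}: samples without design labels: {missing}")
        bad = set(self.design.unique()) - {TREATMENT, CONTROL}
        if bad:
            raise ValueError(f"experiment {self.id}: unknown conditions {sorted(bad)}")

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.expression.columns if self.design.get(s) == condition]


@dataclass
class ExperimentSet:
    """Ordered collection of experiments sharing one gene universe."""

    experiments: list[Experiment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.experiments:
            ref = self.experiments[0].expression.index
            for exp in self.experiments[1:]:
                if not exp.expression.index.equals(ref):
                    raise ValueError(
                        f"experiment {exp.id} does not share the gene universe/order"
                    )

    def __iter__(self):
        return iter(self.experiments)

    def __len__(self) -> int:
        return len(self.experiments)

    @property
    def genes(self) -> pd.Index:
        return self.experiments[0].expression.index

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.experiments]


def fold_change_comparisons(expression: pd.DataFrame, design: pd.Series) -> pd.DataFrame:
    """All pairwise treatment-minus-control log2 ratios.

    One column per (treatment sample, control sample) pair, i.e. k = n_t * n_c
    comparisons, the unpaired Rank Products convention.
    """
    t_samples = [s for s in expression.columns if design.get(s) == TREATMENT]
    c_samples = [s for s in expression.columns if design.get(s) == CONTROL]
    if not t_samples or not c_samples:
        raise ValueError("design must contain at least one treatment and one control sample")
    cols = {}
    for t, c in itertools.product(t_samples, c_samples):
        cols[f"{t}.vs.{c}"] = expression[t].to_numpy() - expression[c].to_numpy()
    return pd.DataFrame(cols, index=expression.index)


def _rank_matrix(ratios: np.ndarray, direction: str) -> np.ndarray:
    """Per-comparison ranks, 1 = most regulated in `direction`; ties averaged."""
    if direction == "up":
        return rankdata(-ratios, axis=0, method="average")
    if direction == "down":
        return rankdata(ratios, axis=0, method="average")
    raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")


def rank_product_statistic(ratios: pd.DataFrame, direction: str) -> pd.Series:
    """Geometric mean of a gene's per-comparison ranks (the RP statistic).

    ``rp`` lies in ``[1, G]``; rp = 1 means top-ranked in every comparison.
    """
    arr = np.asarray(ratios, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 1:
        raise ValueError("ratios must be a gene x comparison matrix with >= 1 column")
    ranks = _rank_matrix(arr, direction)
    rp = np.exp(np.log(ranks).mean(axis=1))
    return pd.Series(rp, index=ratios.index, name="rp")


def permutation_pfp(
    ratios: pd.DataFrame,
    direction: str,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
) -> pd.DataFrame:
    """Permutation E-values and PFP for the rank-product statistic.

    Each of the ``n_perm`` permutations independently shuffles the observed
    rank vector within every comparison column and recomputes G null RP
    values; pooled over permutations,

    ``evalue_g = #{null rp <= rp_g} / n_perm``
    ``pfp_g    = evalue_g / rank_asc(rp_g)``

    E-values of exactly zero are floored at ``1/n_perm`` so finite sampling
    never yields a spuriously perfect call; pfp is made monotone
    non-decreasing along ascending rp (step-up enforcement).  For
    significance calling ``pfp`` is clipped at 1.

    Returns a DataFrame with columns ``rp``, ``evalue``, ``pfp``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    arr = np.asarray(ratios, dtype=float)
    ranks = _rank_matrix(arr, direction)  # G x k
    G, k = ranks.shape
    log_rp_obs = np.log(ranks).sum(axis=1)  # compare on sum-of-log scale

    rng = np.random.default_rng(seed)
    # Null: shuffle each comparison's rank vector independently, n_perm times.
    log_ranks = np.log(ranks)
    null = np.empty((n_perm, G))
    chunk = max(1, min(n_perm, 250))
    for start in range(0, n_perm, chunk):
        stop = min(start + chunk, n_perm)
        block = np.zeros((stop - start, G))
        for j in range(k):
            col = np.broadcast_to(log_ranks[:, j], (stop - start, G)).copy()
            rng.permuted(col, axis=1, out=col)
            block += col
        null[start:stop] = block
    null_sorted = np.sort(null, axis=None)
    counts = np.searchsorted(null_sorted, log_rp_obs, side="right")
    evalue = counts / n_perm
    evalue = np.maximum(evalue, 1.0 / n_perm)

    order_rank = rankdata(log_rp_obs, method="max")  # ascending-rp rank; ties conservative
    pfp = evalue / order_rank
    # Enforce monotonicity in rp (step-up style): a gene's pfp is the running
    # maximum of evalue/rank along ascending rp, so sorting by rp never makes
    # the FDR estimate decrease.
    order = np.argsort(log_rp_obs, kind="stable")
    pfp[order] = np.maximum.accumulate(pfp[order])
    return pd.DataFrame(
        {"rp": np.exp(log_rp_obs / k), "evalue": evalue, "pfp": pfp},
        index=ratios.index,
    )


@dataclass
class DEResult:
    """Per-experiment, per-direction rank-product table with calls."""

    experiment_id: str
    direction: str
    table: pd.DataFrame  # columns rp, evalue, pfp, significant

    @property
    def significant_genes(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


@dataclass
class DECollection:
    """All DEResults of an ExperimentSet plus convenience accessors."""

    results: list[DEResult]
    threshold: float

    def per_experiment(self) -> dict[str, dict[str, DEResult]]:
        out: dict[str, dict[str, DEResult]] = {}
        for r in self.results:
            out.setdefault(r.experiment_id, {})[r.direction] = r
        return out

    def gene_sets(self) -> dict[str, set[str]]:
        """Experiment -> genes significant in either direction."""
        sets: dict[str, set[str]] = {}
        for r in self.results:
            sets.setdefault(r.experiment_id, set()).update(r.significant_genes)
        return sets

    def direction_sets(self) -> dict[str, dict[str, set[str]]]:
        """Experiment -> {'up': genes, 'down': genes}, resolved per gene.

        A gene significant in both directions of one experiment (pathological)
        is assigned the direction with the smaller pfp.
        """
        out: dict[str, dict[str, set[str]]] = {}
        for exp_id, by_dir in self.per_experiment().items():
            up = by_dir["up"].significant_genes if "up" in by_dir else set()
            down = by_dir["down"].significant_genes if "down" in by_dir else set()
            both = up & down
            for g in both:
                if by_dir["up"].table.loc[g, "pfp"] <= by_dir["down"].table.loc[g, "pfp"]:
                    down.discard(g)
                else:
                    up.discard(g)
            out[exp_id] = {"up": up, "down": down}
        return out

    @property
    def union_genes(self) -> set[str]:
        """Genes significant in at least one experiment (the paper-style union list)."""
        union: set[str] = set()
        for s in self.gene_sets().values():
            union |= s
        return union

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for r in self.results:
            t = r.table.copy()
            t.insert(0, "direction", r.direction)
            t.insert(0, "experiment", r.experiment_id)
            t.index.name = "gene"
            frames.append(t.reset_index())
        return pd.concat(frames, ignore_index=True)


def call_de(
    experiments: ExperimentSet,
    threshold: float = 0.05,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> DECollection:
    """Run both directions of the rank-product analysis on every experiment.

    ``significant`` is ``pfp (clipped at 1) <= threshold``.  Sub-seeds for the
    permutation null are spawned deterministically from ``seed``, one per
    (experiment, direction).
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = iter(ss.spawn(2 * len(experiments)))
    results = []
    for exp in experiments:
        ratios = fold_change_comparisons(exp.expression, exp.design)
        for direction in ("up", "down"):
            table = permutation_pfp(ratios, direction, n_perm=n_perm, seed=next(children))
            table["significant"] = np.minimum(table["pfp"], 1.0) <= threshold
            results.append(DEResult(exp.id, direction, table))
    return DECollection(results=results, threshold=threshold)
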