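"""Synthetic multi-experiment nitrate-response universe.

Everything downstream of raw arrays is exercised on data generated here: a
single-rooted GO-style DAG, a gene universe partitioned into families with
within-family protein similarities (emulating BLASTP hits that survived an
E <= 1e-10 filter, scores normalized to [0, 1]), gene -> term annotations in
which family members share a deep term, and a set of small
treatment-vs-control expression experiments.

The central planted structure is *functional degeneracy*: each responsive
function (a deep GO term) is realized in every experiment by one member per
associated gene family, and the contributing member is resampled between
experiments with probability ``1 - redundancy``.  Low redundancy therefore
yields experiments that regulate largely different genes while hitting the
same functions — the contrast the consistency statistics are built to
detect.  Additional planted structure: coexpression modules driven by latent
profiles shared across all samples, promoter motifs for TF -> target
recovery, and a "direct nitrate signal" gene list concentrated in a few
modules.

Defaults emulate a desk-scale version of the study design: 10 experiments of
3 treatment + 3 control replicates over 2000 genes, log2 effect 2.0,
residual sd 0.5, redundancy 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ontology import compute_levels
from .rankprod import Experiment, ExperimentSet

# stage tags for deterministic, independent per-stage RNG streams
_STAGE_DAG = 1
_STAGE_UNIVERSE = 2
_STAGE_ANNOT = 3
_STAGE_EXPR = 4
_STAGE_MOTIF = 6
_STAGE_FLAGS = 7


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stage))))


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic universe; one seed drives every stage."""

    n_genes: int = 2000
    n_families: int = 300
    family_size_mean: int = 4
    n_go_terms: int = 300
    dag_depth: int = 9
    n_experiments: int = 10
    n_treatment_reps: int = 3
    n_control_reps: int = 3
    responsive_terms: int = 5
    redundancy: float = 0.2  # P(same family member contributes in two experiments)
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    n_modules_planted: int = 5
    module_size: int = 40
    module_cor: float = 0.64
    module_scale: float = 2.0  # residual scale of module genes, in units of noise_sd
    motif_planting_rate: float = 0.8
    seed: int = 0
    # secondary knobs (fixed study conditions, rarely touched)
    families_per_term: int = 20
    down_fraction: float = 0.1
    extra_annotations_mean: float = 2.0
    annotation_levels: tuple[int, ...] = (7, 8)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    n_tfs: int = 4
    motif_background_rate: float = 0.02
    direct_signal_hot_modules: int = 4
    direct_signal_hot_rate: float = 0.8
    direct_signal_background_rate: float = 0.02

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_families": self.n_families,
            "family_size_mean": self.family_size_mean, "n_go_terms": self.n_go_terms,
            "dag_depth": self.dag_depth, "n_experiments": self.n_experiments,
            "n_treatment_reps": self.n_treatment_reps, "n_control_reps": self.n_control_reps,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        for name in ("responsive_terms", "n_modules_planted", "module_size", "n_tfs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        fracs = {
            "redundancy": self.redundancy, "module_cor": self.module_cor,
            "motif_planting_rate": self.motif_planting_rate,
            "down_fraction": self.down_fraction,
            "motif_background_rate": self.motif_background_rate,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_modules_planted * self.module_size > self.n_genes:
            raise ValueError("planted modules cannot exceed the gene universe")
        if self.n_go_terms < self.dag_depth + 1:
            raise ValueError("n_go_terms must be >= dag_depth + 1")
        if self.n_tfs > max(self.n_modules_planted, 0) and self.n_modules_planted > 0:
            raise ValueError("n_tfs must be <= n_modules_planted when modules are planted")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:04d}" for i in range(self.n_genes)]


@dataclass
class GroundTruth:
    """Planted structure, for parameter-recovery tests."""

    responsive_gene_sets: dict[str, dict[str, set[str]]]  # exp -> {'up','down'} -> genes
    responsive_term_ids: set[str]
    family_of: pd.Series  # gene -> family id
    module_of: pd.Series  # gene -> planted module id (0 = none)
    tf_targets: dict[str, set[str]]  # TF gene -> true targets
    direct_signal_genes: set[str]

    def de_sets(self) -> dict[str, set[str]]:
        return {e: d["up"] | d["down"] for e, d in self.responsive_gene_sets.items()}


def generate_go_dag(n_terms: int, depth: int, seed: int = 0) -> pd.DataFrame:
    """Random single-rooted DAG as a child -> parent edge list.

    A root-to-leaf chain guarantees levels span 0..depth; remaining terms
    attach at a uniformly drawn level, occasionally with a second parent (a
    genuine DAG, not a tree).  ``n_terms == 1`` (with depth 0) yields a
    single isolated root and an empty edge list.
    """
    if n_terms < 1 or depth < 0:
        raise ValueError("need n_terms >= 1 and depth >= 0")
    if n_terms < depth + 1:
        raise ValueError(f"n_terms={n_terms} cannot span depth {depth}")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), _STAGE_DAG)))
    terms = [f"T{i:04d}" for i in range(n_terms)]
    edges: list[tuple[str, str]] = []
    level: dict[str, int] = {terms[0]: 0}
    for i in range(1, depth + 1):  # backbone chain
        edges.append((terms[i], terms[i - 1]))
        level[terms[i]] = i
    by_level: dict[int, list[str]] = {}
    for t, lv in level.items():
        by_level.setdefault(lv, []).append(t)
    for i in range(depth + 1, n_terms):
        child_level = int(rng.integers(1, depth + 1))
        parent = by_level[child_level - 1][rng.integers(len(by_level[child_level - 1]))]
        edges.append((terms[i], parent))
        # second parent at level >= child_level - 1 keeps the shortest path intact
        if depth >= 1 and rng.random() < 0.25:
            pool = [t for lv in range(child_level - 1, depth) for t in by_level.get(lv, [])
                    if t != parent]
            if pool:
                edges.append((terms[i], pool[rng.integers(len(pool))]))
        level[terms[i]] = child_level
        by_level.setdefault(child_level, []).append(terms[i])
    return pd.DataFrame(edges, columns=["child", "parent"])


def generate_gene_universe(cfg: SyntheticConfig) -> tuple[pd.Series, pd.DataFrame]:
    """Partition genes into families and emit the within-family similarity table.

    Family sizes are 1 + Poisson(mean - 1); genes beyond the drawn families
    become singleton families.  Similarity scores (normalized BLASTP analog)
    exist only for within-family pairs and are emitted symmetrically;
    between-family pairs are absent, i.e. fell below the E-value filter.
    """
    rng = _rng(cfg.seed, _STAGE_UNIVERSE)
    genes = cfg.gene_ids
    if cfg.n_families == 1:  # one family requested: the whole universe
        sizes = np.array([cfg.n_genes])
    else:
        sizes = 1 + rng.poisson(max(cfg.family_size_mean - 1, 0), cfg.n_families)
    family_of = {}
    cursor = 0
    fam = 0
    for s in sizes:
        if cursor >= cfg.n_genes:
            break
        for g in genes[cursor:cursor + s]:
            family_of[g] = fam
        cursor += s
        fam += 1
    for g in genes[cursor:]:  # leftovers: singleton families
        family_of[g] = fam
        fam += 1
    family = pd.Series(family_of, name="family").loc[genes]

    rows = []
    for _, members in family.groupby(family):
        ids = list(members.index)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                score = float(rng.beta(8, 2))
                rows.append((ids[i], ids[j], score))
                rows.append((ids[j], ids[i], score))
    sim = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    return family, sim


@dataclass
class AnnotationPlan:
    """Gene -> term annotations plus the responsive-term wiring."""

    annotations: dict[str, set[str]]
    family_term: dict[int, str]  # family id -> its shared deep term
    responsive_terms: list[str]
    term_families: dict[str, list[int]]  # responsive term -> contributing families


def generate_annotations(
    family_of: pd.Series,
    dag_edges: pd.DataFrame,
    cfg: SyntheticConfig,
) -> AnnotationPlan:
    """Annotate genes so that families share one deep term each.

    Responsive terms are deep terms (levels 7-8 by default) assigned
    ``families_per_term`` families of moderate size (3-4 members) so that
    per-experiment contributions are detectable by enrichment while the
    member identity can still vary.  Every gene additionally receives
    Poisson-distributed random annotations, keeping per-gene annotation
    counts roughly uniform across the universe.
    """
    rng = _rng(cfg.seed, _STAGE_ANNOT)
    levels = compute_levels(dag_edges)
    deep = sorted(t for t, lv in levels.items() if lv in cfg.annotation_levels)
    if not deep:
        maxlv = max(levels.values())
        deep = sorted(t for t, lv in levels.items() if lv >= max(maxlv - 1, 1))
    non_root = sorted(t for t, lv in levels.items() if lv > 0)

    # responsive terms must be leaves: interior terms accumulate the
    # annotations of their whole subtree under propagation, drowning the
    # planted signal in a huge background
    parents = set(dag_edges["parent"]) if len(dag_edges) else set()
    deep_leaves = [t for t in deep if t not in parents] or deep
    n_resp = min(cfg.responsive_terms, len(deep_leaves))
    responsive = ([str(t) for t in rng.choice(deep_leaves, size=n_resp, replace=False)]
                  if n_resp else [])

    fam_sizes = family_of.groupby(family_of).size()
    eligible = [int(f) for f in fam_sizes.index[(fam_sizes >= 3) & (fam_sizes <= 4)]]
    if len(eligible) < n_resp * cfg.families_per_term:
        eligible += [int(f) for f in fam_sizes.index[fam_sizes >= 2] if int(f) not in set(eligible)]
    rng.shuffle(eligible)

    term_families: dict[str, list[int]] = {t: [] for t in responsive}
    it = iter(eligible)
    for t in responsive:
        for _ in range(cfg.families_per_term):
            try:
                term_families[t].append(next(it))
            except StopIteration:
                break

    family_term: dict[int, str] = {}
    for t, fams in term_families.items():
        for f in fams:
            family_term[f] = t
    background_pool = [t for t in deep if t not in set(responsive)] or non_root
    for f in fam_sizes.index:
        f = int(f)
        if f not in family_term:
            family_term[f] = background_pool[rng.integers(len(background_pool))]

    annotations: dict[str, set[str]] = {}
    for g in family_of.index:
        terms = {family_term[int(family_of[g])]}
        n_extra = rng.poisson(cfg.extra_annotations_mean)
        if n_extra:
            terms.update(rng.choice(non_root, size=min(n_extra, len(non_root)), replace=False))
        annotations[g] = terms
    return AnnotationPlan(annotations, family_term, responsive, term_families)


@dataclass
class SyntheticBundle:
    """Everything a full pipeline run consumes, plus the ground truth."""

    cfg: SyntheticConfig
    dag_edges: pd.DataFrame
    levels: dict[str, int]
    family_of: pd.Series
    similarity: pd.DataFrame
    plan: AnnotationPlan
    experiments: ExperimentSet
    truth: GroundTruth
    motif_table: pd.DataFrame  # genes x motifs, boolean
    tf_motifs: dict[str, list[str]]  # TF gene -> motif ids

    @property
    def annotations(self) -> dict[str, set[str]]:
        return self.plan.annotations

    @property
    def tf_list(self) -> list[str]:
        return sorted(self.tf_motifs)


def _assign_modules_across_families(
    cfg: SyntheticConfig,
    plan: AnnotationPlan,
    members_pool: dict[int, list[str]],
    rng: np.random.Generator,
) -> pd.Series:
    """Plant module labels on responsive-family members, one term per module.

    Modules are planted among responsive-family genes so the planted
    coexpression structure lives inside the gene set a DE-driven network
    will contain, and each module draws its members from the families of a
    single responsive term so detected modules carry a coherent function —
    mirroring functionally coherent coexpression modules in real data.
    """
    module_of = pd.Series(0, index=pd.Index(cfg.gene_ids, name="gene"), name="module")
    need = cfg.n_modules_planted * cfg.module_size
    if need == 0:
        return module_of
    used: set[str] = set()
    terms = plan.responsive_terms
    for m in range(1, cfg.n_modules_planted + 1):
        # each module is built from the families of one responsive term, so
        # detected modules carry a coherent planted function
        fams = (list(rng.permutation(plan.term_families[terms[(m - 1) % len(terms)]]))
                if terms else [])
        taken = 0
        while taken < cfg.module_size and fams:
            progress = False
            for f in fams:
                if taken >= cfg.module_size:
                    break
                free = [g for g in members_pool[int(f)] if g not in used]
                if not free:
                    continue
                g = free[int(rng.integers(len(free)))]
                module_of[g] = m
                used.add(g)
                taken += 1
                progress = True
            if not progress:
                break
        if taken < cfg.module_size:  # top up from genes outside the families
            rest = [g for g in cfg.gene_ids if g not in used and module_of[g] == 0]
            for g in rng.permutation(rest)[:cfg.module_size - taken]:
                module_of[g] = m
                used.add(g)
    return module_of


def generate_experiments(cfg: SyntheticConfig) -> tuple[ExperimentSet, GroundTruth]:
    """Generate the experiment set and ground truth (see :func:`generate_bundle`)."""
    bundle = generate_bundle(cfg)
    return bundle.experiments, bundle.truth


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Build the complete synthetic universe deterministically from ``cfg``."""
    dag_edges = generate_go_dag(cfg.n_go_terms, cfg.dag_depth, seed=cfg.seed)
    levels = compute_levels(dag_edges) if len(dag_edges) else {"T0000": 0}
    family_of, similarity = generate_gene_universe(cfg)
    plan = generate_annotations(family_of, dag_edges, cfg)

    rng = _rng(cfg.seed, _STAGE_EXPR)
    genes = cfg.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    members_pool = {int(f): list(m.index) for f, m in family_of.groupby(family_of)}
    module_of = _assign_modules_across_families(cfg, plan, members_pool, rng)

    n_per_exp = cfg.n_treatment_reps + cfg.n_control_reps
    total_samples = cfg.n_experiments * n_per_exp
    latents = rng.standard_normal((max(cfg.n_modules_planted, 1), total_samples))
    # Balance the module latent within every condition group (zero mean per
    # group, variance restored) so planted coexpression is orthogonal to the
    # planted treatment effect: module genes co-vary but are not pseudo-DE.
    for e in range(cfg.n_experiments):
        s0 = e * n_per_exp
        for lo, hi in ((s0, s0 + cfg.n_treatment_reps),
                       (s0 + cfg.n_treatment_reps, s0 + n_per_exp)):
            block = latents[:, lo:hi]
            if hi - lo >= 2:
                centered = block - block.mean(axis=1, keepdims=True)
                latents[:, lo:hi] = centered * np.sqrt((hi - lo) / (hi - lo - 1))
            else:
                latents[:, lo:hi] = 0.0

    # canonical contributing member per (responsive term, family)
    members_by_family = {int(f): list(m.index) for f, m in family_of.groupby(family_of)}
    canonical: dict[tuple[str, int], str] = {}
    for t, fams in plan.term_families.items():
        for f in fams:
            mem = members_by_family[f]
            canonical[(t, f)] = mem[rng.integers(len(mem))]

    experiments = []
    responsive_gene_sets: dict[str, dict[str, set[str]]] = {}
    for e in range(cfg.n_experiments):
        exp_id = f"exp{e + 1:02d}"
        t_names = [f"{exp_id}_T{j + 1}" for j in range(cfg.n_treatment_reps)]
        c_names = [f"{exp_id}_C{j + 1}" for j in range(cfg.n_control_reps)]
        samples = t_names + c_names
        s0 = e * n_per_exp

        noise = rng.standard_normal((cfg.n_genes, n_per_exp))
        expr = baseline[:, None] + cfg.noise_sd * noise
        # planted coexpression: latent shared across ALL samples of the study
        for m in range(1, cfg.n_modules_planted + 1):
            rows = np.flatnonzero(module_of.to_numpy() == m)
            lat = latents[m - 1, s0:s0 + n_per_exp]
            mixed = (np.sqrt(cfg.module_cor) * lat[None, :]
                     + np.sqrt(1.0 - cfg.module_cor) * noise[rows, :])
            # module genes are noisier overall (module_scale) so the shared
            # latent stays visible next to planted treatment shifts
            expr[rows, :] = (baseline[rows, None]
                             + cfg.noise_sd * cfg.module_scale * mixed)

        up: set[str] = set()
        down: set[str] = set()
        for t in plan.responsive_terms:
            for f in plan.term_families[t]:
                g = canonical[(t, f)]
                if rng.random() >= cfg.redundancy:
                    mem = members_by_family[f]
                    g = mem[rng.integers(len(mem))]
                (down if rng.random() < cfg.down_fraction else up).add(g)
        down -= up
        n_t = cfg.n_treatment_reps
        for g in up:
            expr[gene_pos[g], :n_t] += cfg.effect_log2fc
        for g in down:
            expr[gene_pos[g], :n_t] -= cfg.effect_log2fc

        frame = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
        design = pd.Series(
            ["treatment"] * cfg.n_treatment_reps + ["control"] * cfg.n_control_reps,
            index=samples, name="condition",
        )
        experiments.append(Experiment(exp_id, frame, design))
        responsive_gene_sets[exp_id] = {"up": up, "down": down}

    # promoter motifs: one motif per TF, planted on module co-members
    rng_m = _rng(cfg.seed, _STAGE_MOTIF)
    tf_motifs: dict[str, list[str]] = {}
    tf_targets: dict[str, set[str]] = {}
    motif_cols: dict[str, np.ndarray] = {}
    for i in range(cfg.n_tfs):
        if cfg.n_modules_planted:
            module_genes = list(module_of.index[module_of == i + 1])
        else:
            module_genes = list(rng_m.choice(genes, size=min(40, cfg.n_genes), replace=False))
        tf = module_genes[0]
        motif = f"M_{tf}"
        present = rng_m.random(cfg.n_genes) < cfg.motif_background_rate
        targets = set()
        for g in module_genes[1:]:
            if rng_m.random() < cfg.motif_planting_rate:
                present[gene_pos[g]] = True
                targets.add(g)
        present[gene_pos[tf]] = False
        tf_motifs[tf] = [motif]
        tf_targets[tf] = targets
        motif_cols[motif] = present
    motif_table = pd.DataFrame(motif_cols, index=pd.Index(genes, name="gene"), dtype=bool)

    rng_f = _rng(cfg.seed, _STAGE_FLAGS)
    hot = list(range(1, min(cfg.direct_signal_hot_modules, cfg.n_modules_planted) + 1))
    direct = plant_flagged_genes(
        module_of, hot, cfg.direct_signal_hot_rate,
        cfg.direct_signal_background_rate, rng=rng_f,
    )

    truth = GroundTruth(
        responsive_gene_sets=responsive_gene_sets,
        responsive_term_ids=set(plan.responsive_terms),
        family_of=family_of,
        module_of=module_of,
        tf_targets=tf_targets,
        direct_signal_genes=direct,
    )
    return SyntheticBundle(
        cfg=cfg, dag_edges=dag_edges, levels=levels, family_of=family_of,
        similarity=similarity, plan=plan, experiments=ExperimentSet(experiments),
        truth=truth, motif_table=motif_table, tf_motifs=tf_motifs,
    )


def plant_flagged_genes(
    module_of: pd.Series,
    hot_modules: list[int],
    hot_rate: float = 0.8,
    background_rate: float = 0.02,
    rng: np.random.Generator | int | None = 0,
) -> set[str]:
    """Flag genes (e.g. as direct-nitrate-signal) concentrated in hot modules."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    hot = set(hot_modules)
    flagged = set()
    for g, m in module_of.items():
        rate = hot_rate if m in hot else background_rate
        if rng.random() < rate:
            flagged.add(g)
    return flagged


def generate_module_expression(
    n_modules: int = 5,
    module_size: int = 40,
    n_samples: int = 60,
    module_cor: float = 0.64,
    n_background: int = 0,
    noise_sd: float = 1.0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Stand-alone planted-module expression matrix for network benchmarks.

    Each module gene is ``sqrt(c) * latent + sqrt(1-c) * noise`` so the
    within-module Pearson correlation is analytically ``module_cor``.
    Background genes (label 0) are pure noise.  Returns (expression,
    module labels).
    """
    rng = np.random.default_rng(seed)
    n_genes = n_modules * module_size + n_background
    genes = pd.Index([f"G{i:04d}" for i in range(n_genes)], name="gene")
    labels = np.zeros(n_genes, dtype=int)
    noise = rng.standard_normal((n_genes, n_samples))
    mixed = noise.copy()
    for m in range(n_modules):
        rows = slice(m * module_size, (m + 1) * module_size)
        labels[rows] = m + 1
        lat = rng.standard_normal(n_samples)
        mixed[rows] = (np.sqrt(module_cor) * lat[None, :]
                       + np.sqrt(1.0 - module_cor) * noise[rows])
    baseline = rng.normal(baseline_mean, baseline_sd, n_genes)
    expr = pd.DataFrame(baseline[:, None] + noise_sd * mixed, index=genes,
                        columns=[f"S{j + 1:03d}" for j in range(n_samples)])
    return expr, pd.Series(labels, index=genes, name="module")


@dataclass
class TfBenchmark:
    """Planted TF -> target structure over a modular expression matrix."""

    expression: pd.DataFrame
    module_of: pd.Series
    motif_table: pd.DataFrame
    tf_motifs: dict[str, list[str]]
    true_edges: set[tuple[str, str]]


def generate_tf_benchmark(
    n_tfs: int = 4,
    module_size: int = 40,
    n_samples: int = 60,
    module_cor: float = 0.85,
    motif_rate: float = 0.8,
    background_rate: float = 0.02,
    n_background: int = 80,
    seed: int = 0,
) -> TfBenchmark:
    """Each TF sits in its own coexpression module; its motif marks true targets.

    ``module_cor`` defaults high enough that within-module topological
    overlap clears the 0.10 display threshold at beta = 7.
    """
    expr, module_of = generate_module_expression(
        n_modules=n_tfs, module_size=module_size, n_samples=n_samples,
        module_cor=module_cor, n_background=n_background, seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), _STAGE_MOTIF)))
    genes = expr.index
    pos = {g: i for i, g in enumerate(genes)}
    tf_motifs: dict[str, list[str]] = {}
    true_edges: set[tuple[str, str]] = set()
    cols: dict[str, np.ndarray] = {}
    for m in range(1, n_tfs + 1):
        members = list(module_of.index[module_of == m])
        tf = members[0]
        motif = f"M_{tf}"
        present = rng.random(len(genes)) < background_rate
        for g in members[1:]:
            if rng.random() < motif_rate:
                present[pos[g]] = True
                true_edges.add((tf, g))
        present[pos[tf]] = False
        tf_motifs[tf] = [motif]
        cols[motif] = present
    motif_table = pd.DataFrame(cols, index=genes, dtype=bool)
    return TfBenchmark(expr, module_of, motif_table, tf_motifs, true_edges)


@dataclass
class SimulatedSharedTerm:
    """One shared GO term: annotated genes, per-experiment contributors, similarity."""

    term: str
    annotated: set[str]
    contributors: dict[str, set[str]]
    similarity: pd.DataFrame  # gene_a, gene_b, score (symmetric)


def simulate_shared_terms(
    n_terms: int,
    mode: str = "planted",
    n_families: int = 6,
    family_size: int = 4,
    n_extra: int = 20,
    n_experiments: int = 2,
    seed: int = 0,
) -> list[SimulatedSharedTerm]:
    """Simulate shared terms for calibrating the protein-similarity test.

    ``planted``: the term's genes fall into families with high within-family
    similarity; each experiment contributes a *different* member per family
    (the degenerate alternative).  ``null``: similarity values are assigned
    i.i.d. across gene pairs and contributors are drawn uniformly, making
    observed cross-experiment pairs exchangeable with random pairs — the
    correct null for type-I calibration.
    """
    if mode not in ("planted", "null"):
        raise ValueError("mode must be 'planted' or 'null'")
    rng = np.random.default_rng(seed)
    out = []
    n_pool = n_families * family_size + n_extra
    pair_rate = (n_families * family_size * (family_size - 1) / 2) / (n_pool * (n_pool - 1) / 2)
    for t in range(n_terms):
        genes = [f"T{t}_g{i}" for i in range(n_pool)]
        rows = []
        if mode == "planted":
            for f in range(n_families):
                fam = genes[f * family_size:(f + 1) * family_size]
                for i in range(family_size):
                    for j in range(i + 1, family_size):
                        s = float(rng.beta(8, 2))
                        rows.append((fam[i], fam[j], s))
                        rows.append((fam[j], fam[i], s))
            # degenerate alternative: experiments recruit distinct members
            perms = [rng.permutation(family_size) for _ in range(n_families)]
            contributors = {
                f"e{e}": {
                    genes[f * family_size + int(perms[f][e % family_size])]
                    for f in range(n_families)
                }
                for e in range(n_experiments)
            }
        else:
            for i in range(n_pool):
                for j in range(i + 1, n_pool):
                    if rng.random() < pair_rate:
                        s = float(rng.beta(8, 2))
                        rows.append((genes[i], genes[j], s))
                        rows.append((genes[j], genes[i], s))
            contributors = {
                f"e{e}": set(rng.choice(genes, size=n_families, replace=False))
                for e in range(n_experiments)
            }
        sim = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
        out.append(SimulatedSharedTerm(f"simterm{t}", set(genes), contributors, sim))
    return out
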