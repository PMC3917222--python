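"""End-to-end orchestration: generate -> DE -> consistency -> network.

Each stage reads its inputs from the run directory and writes tables plus an
entry in a machine-readable manifest (JSON) that records the stage
parameters and a SHA-256 digest of every output file, so two runs with the
same configuration can be compared byte-for-byte.  All stochastic stages
receive sub-seeds derived deterministically from the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consistency as cons
from . import io as nio
from . import network as net
from . import rankprod as rp
from .ontology import GoResources, filter_by_level
from .synthetic import SyntheticConfig, generate_bundle

STAGES = ("generate", "de", "consistency", "network")


@dataclass
class PipelineConfig:
    """Declarative configuration of a full run."""

    outdir: str = "nitronet_run"
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    pfp_threshold: float = 0.05
    n_perm_de: int = 1000
    enrichment_alpha: float = 0.05
    go_level_filter: tuple[int, ...] = (7, 8)
    propagate_annotations: bool = True
    overlap_metric: str = "jaccard"
    max_combos: int = 10_000
    n_perm_similarity: int = 1000
    n_random_lists: int = 1000
    # min module size scaled to the desk-scale network (~800 genes vs
    # thousands on a full array platform)
    coexpr: net.CoexprParams = field(
        default_factory=lambda: net.CoexprParams(min_module_size=15))
    beta: int | str = 7  # the study's soft power; "auto" -> pick_soft_threshold
    candidate_powers: tuple[int, ...] = tuple(range(1, 13))

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticConfig(**self.synthetic)
        if isinstance(self.coexpr, dict):
            self.coexpr = net.CoexprParams(**self.coexpr)
        # the master seed drives the generator too, unless set explicitly
        if self.synthetic.seed != self.seed:
            self.synthetic = dataclasses.replace(self.synthetic, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["go_level_filter"] = list(self.go_level_filter)
        d["candidate_powers"] = list(self.candidate_powers)
        d["synthetic"]["annotation_levels"] = list(self.synthetic.annotation_levels)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("go_level_filter", "candidate_powers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "synthetic" in raw and "annotation_levels" in raw["synthetic"]:
            raw["synthetic"]["annotation_levels"] = tuple(
                raw["synthetic"]["annotation_levels"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig):
        self.outdir = outdir
        self.path = outdir / "manifest.json"
        if self.path.exists():
            with open(self.path) as fh:
                self.data = json.load(fh)
        else:
            self.data = {"config": config.to_dict(), "stages": {}}

    def record(self, stage: str, params: dict, outputs: list[Path],
               status: str = "ok") -> None:
        # paths relative to the run dir so identical runs compare equal
        self.data["stages"][stage] = {
            "status": status,
            "params": params,
            "outputs": {str(p.relative_to(self.outdir)): _sha256(p)
                        for p in outputs if p.exists()},
        }
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, sort_keys=True)


def _data_dir(outdir: Path) -> Path:
    return outdir / "data"


def stage_generate(config: PipelineConfig) -> list[Path]:
    """Write the synthetic bundle (inputs + ground truth) to the run directory."""
    outdir = Path(config.outdir)
    data = _data_dir(outdir)
    data.mkdir(parents=True, exist_ok=True)
    bundle = generate_bundle(config.synthetic)
    written = nio.write_experiment_set(bundle.experiments, data)

    p = data / "go_dag.tsv"
    nio.write_dag_edges(bundle.dag_edges, p)
    written.append(p)
    p = data / "annotations.gmt"
    nio.write_gmt(nio.annotations_to_term_map(bundle.annotations), p)
    written.append(p)
    p = data / "similarity.tsv"
    nio.write_similarity(bundle.similarity, p)
    written.append(p)
    p = data / "motifs.tsv"
    nio.write_motifs(bundle.motif_table, p)
    written.append(p)
    p = data / "tf_motifs.tsv"
    pd.DataFrame([(tf, m) for tf, ms in sorted(bundle.tf_motifs.items()) for m in ms],
                 columns=["tf", "motif"]).to_csv(p, sep="\t", index=False)
    written.append(p)
    p = data / "direct_signal_genes.tsv"
    nio.write_gene_list(bundle.truth.direct_signal_genes, p)
    written.append(p)

    truth_dir = data / "truth"
    truth_dir.mkdir(exist_ok=True)
    rows = [(e, g, d) for e, dirs in bundle.truth.responsive_gene_sets.items()
            for d, genes in dirs.items() for g in sorted(genes)]
    p = truth_dir / "responsive_genes.tsv"
    pd.DataFrame(rows, columns=["experiment", "gene", "direction"]).to_csv(
        p, sep="\t", index=False)
    written.append(p)
    p = truth_dir / "responsive_terms.tsv"
    pd.Series(sorted(bundle.truth.responsive_term_ids), name="term").to_csv(
        p, sep="\t", index=False)
    written.append(p)
    p = truth_dir / "family_of.tsv"
    bundle.family_of.to_csv(p, sep="\t", index_label="gene")
    written.append(p)
    p = truth_dir / "module_of.tsv"
    bundle.truth.module_of.to_csv(p, sep="\t", index_label="gene")
    written.append(p)
    p = truth_dir / "tf_targets.tsv"
    pd.DataFrame([(tf, g) for tf, gs in sorted(bundle.truth.tf_targets.items())
                  for g in sorted(gs)], columns=["tf", "target"]).to_csv(
        p, sep="\t", index=False)
    written.append(p)

    manifest = _Manifest(outdir, config)
    manifest.record("generate", {"synthetic": config.to_dict()["synthetic"]}, written)
    return written


def stage_de(config: PipelineConfig) -> list[Path]:
    """Rank-product DE on every experiment; writes per-gene tables and the union list."""
    outdir = Path(config.outdir)
    data = _data_dir(outdir)
    experiments = nio.read_experiment_set(data)
    seed = np.random.SeedSequence((config.seed, 10))
    de = rp.call_de(experiments, threshold=config.pfp_threshold,
                    n_perm=config.n_perm_de, seed=seed)
    de_dir = outdir / "de"
    de_dir.mkdir(parents=True, exist_ok=True)
    written = []
    p = de_dir / "de_results.tsv"
    de.to_frame().to_csv(p, sep="\t", index=False)
    written.append(p)
    p = de_dir / "union_genes.tsv"
    nio.write_gene_list(de.union_genes, p)
    written.append(p)
    p = de_dir / "direction_sets.tsv"
    rows = [(e, g, d) for e, dirs in de.direction_sets().items()
            for d, genes in dirs.items() for g in sorted(genes)]
    pd.DataFrame(rows, columns=["experiment", "gene", "direction"]).to_csv(
        p, sep="\t", index=False)
    written.append(p)
    _Manifest(outdir, config).record(
        "de", {"threshold": config.pfp_threshold, "n_perm": config.n_perm_de}, written)
    return written


def _load_resources(config: PipelineConfig) -> GoResources:
    data = _data_dir(Path(config.outdir))
    dag = nio.read_dag_edges(data / "go_dag.tsv")
    annotations = nio.term_map_to_annotations(nio.read_gmt(data / "annotations.gmt"))
    return GoResources.from_tables(dag, annotations,
                                   propagate=config.propagate_annotations)


def _load_direction_sets(config: PipelineConfig) -> dict[str, dict[str, set[str]]]:
    df = pd.read_csv(Path(config.outdir) / "de" / "direction_sets.tsv", sep="\t")
    out: dict[str, dict[str, set[str]]] = {}
    for (e, d), sub in df.groupby(["experiment", "direction"]):
        out.setdefault(str(e), {"up": set(), "down": set()})[str(d)] = set(
            sub["gene"].astype(str))
    return out


def _per_experiment_enrichment(
    config: PipelineConfig,
    resources: GoResources,
    de_gene_sets: dict[str, set[str]],
    universe: set[str],
) -> tuple[dict[str, set[str]], dict[str, pd.DataFrame]]:
    from .ontology import fisher_enrichment

    term_sets = {}
    tables = {}
    for exp_id, genes in sorted(de_gene_sets.items()):
        rows = fisher_enrichment(genes & universe, universe, resources,
                                 alpha=config.enrichment_alpha)
        tables[exp_id] = rows
        term_sets[exp_id] = set(rows.loc[rows["enriched"], "term"])
    return term_sets, tables


def stage_consistency(config: PipelineConfig) -> list[Path]:
    """Consistency ranking, overlap curves, control analyses, similarity test."""
    outdir = Path(config.outdir)
    data = _data_dir(outdir)
    resources = _load_resources(config)
    direction_sets = _load_direction_sets(config)
    de_gene_sets = {e: d["up"] | d["down"] for e, d in direction_sets.items()}
    experiments = nio.read_experiment_set(data)
    universe = set(experiments.genes)

    out = outdir / "consistency"
    out.mkdir(parents=True, exist_ok=True)
    written = []

    ranking = cons.consistency_ranking(direction_sets)
    p = out / "consistency_ranking.tsv"
    ranking.to_csv(p, sep="\t", index=False)
    written.append(p)

    term_sets, tables = _per_experiment_enrichment(config, resources,
                                                   de_gene_sets, universe)
    p = out / "enrichment_per_experiment.tsv"
    pd.concat([t.assign(experiment=e) for e, t in tables.items()],
              ignore_index=True).to_csv(p, sep="\t", index=False)
    written.append(p)

    curves = cons.overlap_curves(
        de_gene_sets, term_sets, max_combos=config.max_combos,
        seed=int(np.random.SeedSequence((config.seed, 20)).generate_state(1)[0] % (2**31)),
        metric=config.overlap_metric)
    p = out / "overlap_curves.tsv"
    curves.to_csv(p, sep="\t", index=False)
    written.append(p)

    shared = cons.pairwise_shared_terms(term_sets)

    level_ctl = cons.level_distribution_control(term_sets, shared, resources.levels)
    p = out / "level_control.tsv"
    pd.DataFrame({"total": level_ctl.total_hist,
                  "shared": level_ctl.shared_hist}).fillna(0.0).to_csv(
        p, sep="\t", index_label="level")
    written.append(p)

    union_genes = set().union(*de_gene_sets.values()) if de_gene_sets else set()
    rand_ctl = cons.random_list_annotation_control(
        universe, resources.annotations, list_size=max(len(union_genes), 1),
        n_iter=config.n_random_lists,
        seed=int(np.random.SeedSequence((config.seed, 21)).generate_state(1)[0] % (2**31)),
        observed_genes=union_genes)
    p = out / "random_list_control.tsv"
    pd.DataFrame([{
        "mean_terms_random": rand_ctl.mean, "sd_terms_random": rand_ctl.sd,
        "observed_terms": rand_ctl.observed,
        "observed_quantile": rand_ctl.observed_quantile,
        "list_size": len(union_genes), "n_iter": config.n_random_lists,
    }]).to_csv(p, sep="\t", index=False)
    written.append(p)

    overlap = cons.shared_term_gene_overlap(shared, de_gene_sets,
                                            resources.term_to_genes,
                                            metric=config.overlap_metric)
    p = out / "shared_term_gene_overlap.tsv"
    overlap.table.to_csv(p, sep="\t", index=False)
    written.append(p)

    sim_table = cons.SimilarityTable(nio.read_similarity(data / "similarity.tsv"))
    sim_results = cons.similarity_tests_for_shared_terms(
        shared, de_gene_sets, resources.term_to_genes, sim_table,
        n_perm=config.n_perm_similarity,
        seed=int(np.random.SeedSequence((config.seed, 22)).generate_state(1)[0] % (2**31)),
        alpha=config.enrichment_alpha)
    p = out / "similarity_tests.tsv"
    sim_results.to_csv(p, sep="\t", index=False)
    written.append(p)

    tested = sim_results[~sim_results["skipped"]]
    summary = {
        "n_union_de_genes": len(union_genes),
        "mean_pairwise_gene_overlap_pct": float(
            curves.loc[curves["m"] == 2, "gene_overlap_pct"].iloc[0]),
        "mean_pairwise_go_overlap_pct": float(
            curves.loc[curves["m"] == 2, "go_overlap_pct"].iloc[0]),
        "shared_term_gene_overlap_pct": overlap.grand_mean_pct,
        "level_tv_distance": level_ctl.tv_distance,
        "similarity_significant_pct": (100.0 * tested["significant"].mean()
                                       if len(tested) else float("nan")),
        "n_shared_terms_tested": int(len(tested)),
    }
    p = out / "summary.json"
    with open(p, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    written.append(p)

    _Manifest(outdir, config).record("consistency", {
        "enrichment_alpha": config.enrichment_alpha,
        "overlap_metric": config.overlap_metric,
        "max_combos": config.max_combos,
        "n_perm_similarity": config.n_perm_similarity,
        "n_random_lists": config.n_random_lists,
    }, written)
    return written


def network_profiles(experiments: rp.ExperimentSet, genes: set[str]) -> pd.DataFrame:
    """Expression of `genes` across all samples, median-centered per experiment.

    Centering removes per-experiment location (batch) effects so that
    correlations reflect co-variation within and across experiments.
    """
    blocks = []
    ordered = [g for g in experiments.genes if g in genes]
    for exp in experiments:
        block = exp.expression.loc[ordered]
        blocks.append(block.sub(block.median(axis=1), axis=0))
    return pd.concat(blocks, axis=1)


def stage_network(config: PipelineConfig) -> list[Path]:
    """Coexpression network over the union DE genes: modules, hubs, TF edges."""
    outdir = Path(config.outdir)
    data = _data_dir(outdir)
    experiments = nio.read_experiment_set(data)
    union_genes = nio.read_gene_list(outdir / "de" / "union_genes.tsv")
    resources = _load_resources(config)

    out = outdir / "network"
    out.mkdir(parents=True, exist_ok=True)
    written = []

    profiles = network_profiles(experiments, union_genes)
    if config.beta == "auto":
        beta, fit = net.pick_soft_threshold(profiles, list(config.candidate_powers),
                                            config.coexpr.rsq_target)
    else:
        beta = int(config.beta)
        _, fit = net.pick_soft_threshold(profiles, list(config.candidate_powers),
                                         config.coexpr.rsq_target)
    p = out / "soft_threshold_fit.tsv"
    fit.to_csv(p, sep="\t", index=False)
    written.append(p)

    params = dataclasses.replace(config.coexpr, beta=beta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance genes possible in small runs
        adjacency = net.pearson_adjacency(profiles, beta=beta)
    to = net.topological_overlap(adjacency)
    module_of = net.detect_modules(to, params, genes=profiles.index)
    p = out / "modules.tsv"
    module_of.to_csv(p, sep="\t", index_label="gene")
    written.append(p)

    edges, degrees, hubs = net.threshold_and_hubs(to, module_of,
                                                  params.edge_threshold)
    p = out / "edges.tsv"
    edges.to_csv(p, sep="\t", index=False)
    written.append(p)
    p = out / "network.sif"
    nio.write_sif(edges[["gene_a", "gene_b"]], p)
    written.append(p)
    p = out / "network.graphml"
    nio.write_graphml(edges, p, module_of)
    written.append(p)
    p = out / "degrees.tsv"
    degrees.to_csv(p, sep="\t", index_label="gene")
    written.append(p)
    p = out / "hubs.tsv"
    hubs.to_csv(p, sep="\t", index=False)
    written.append(p)

    enr = net.module_enrichment(module_of, resources, universe=set(profiles.index),
                                alpha=config.enrichment_alpha)
    if config.go_level_filter:
        enr = pd.concat([
            enr[~enr["enriched"]],
            filter_by_level(enr[enr["enriched"]], allowed=set(config.go_level_filter)),
        ]).sort_index() if len(enr) else enr
    p = out / "module_enrichment.tsv"
    enr.to_csv(p, sep="\t", index=False)
    written.append(p)

    flagged = nio.read_gene_list(data / "direct_signal_genes.tsv")
    overlay = net.overlay_gene_list(module_of, flagged)
    p = out / "direct_signal_overlay.tsv"
    overlay.to_csv(p, sep="\t", index=False)
    written.append(p)

    tf_map = pd.read_csv(data / "tf_motifs.tsv", sep="\t")
    tf_motifs = {str(tf): list(sub["motif"].astype(str))
                 for tf, sub in tf_map.groupby("tf")}
    motif_table = nio.read_motifs(data / "motifs.tsv", genes=list(profiles.index))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # TFs may be absent from the DE network
        tf_edges, tf_ranking = net.tf_target_subnetwork(
            to, profiles.index, tf_motifs, motif_table, params,
            alpha=config.enrichment_alpha)
    p = out / "tf_edges.tsv"
    tf_edges.to_csv(p, sep="\t", index=False)
    written.append(p)
    p = out / "tf_ranking.tsv"
    tf_ranking.to_csv(p, sep="\t", index=False)
    written.append(p)

    _Manifest(outdir, config).record("network", {
        "beta": beta, "beta_mode": str(config.beta),
        "edge_threshold": params.edge_threshold,
        "min_module_size": params.min_module_size,
        "cut_height_quantile": params.cut_height_quantile,
    }, written)
    return written


@dataclass
class ValidationIssue:
    kind: str
    detail: str


def validate_inputs(config: PipelineConfig) -> list[ValidationIssue]:
    """Report-only cross-check of the run directory's input files."""
    issues: list[ValidationIssue] = []
    data = _data_dir(Path(config.outdir))
    required = ["design.tsv", "go_dag.tsv", "annotations.gmt", "similarity.tsv",
                "motifs.tsv"]
    for name in required:
        if not (data / name).exists():
            issues.append(ValidationIssue("missing-file", str(data / name)))
    if issues:
        return issues
    try:
        experiments = nio.read_experiment_set(data)
        genes = set(experiments.genes)
    except (nio.MalformedTableError, FileNotFoundError, ValueError) as exc:
        return issues + [ValidationIssue("malformed", str(exc))]
    for name, reader, extract in [
        ("annotations.gmt", nio.read_gmt,
         lambda t2g: {g for gs in t2g.values() for g in gs}),
        ("similarity.tsv", nio.read_similarity,
         lambda df: set(df["gene_a"]) | set(df["gene_b"])),
        ("motifs.tsv", lambda p: nio.read_motifs(p), lambda df: set(df.index)),
    ]:
        try:
            obj = reader(data / name)
        except nio.MalformedTableError as exc:
            issues.append(ValidationIssue("malformed", str(exc)))
            continue
        orphans = sorted(extract(obj) - genes)
        for g in orphans:
            issues.append(ValidationIssue("orphan-gene", f"{name}: {g}"))
    return issues


def run_pipeline(config: PipelineConfig,
                 stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in dependency order; returns the run directory.

    A stage failure is recorded in the manifest (partial outputs retained)
    and re-raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    funcs = {"generate": stage_generate, "de": stage_de,
             "consistency": stage_consistency, "network": stage_network}
    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            funcs[stage](config)
        except Exception as exc:
            _Manifest(outdir, config).record(stage, {"error": str(exc)}, [],
                                             status="failed")
            raise
    return outdir
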