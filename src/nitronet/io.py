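"""Readers and writers for the pipeline's plain-text formats.

Expression matrices, design tables, DAG edge lists, similarity and motif
tables are tab-separated; gene sets use GMT; networks export to SIF plus an
edge-attribute TSV and GraphML (via networkx), consumable by standard graph
viewers.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .rankprod import Experiment, ExperimentSet


class MalformedTableError(ValueError):
    """A TSV row does not match the expected column count; reports the row number."""


def write_expression(expression: pd.DataFrame, path: str | Path) -> None:
    expression.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_design(designs: dict[str, pd.Series], path: str | Path) -> None:
    """One row per sample: sample, experiment, condition."""
    rows = []
    for exp_id, design in designs.items():
        for sample, condition in design.items():
            rows.append((sample, exp_id, condition))
    pd.DataFrame(rows, columns=["sample", "experiment", "condition"]).to_csv(
        path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"sample", "experiment", "condition"}
    if not expected <= set(df.columns):
        raise MalformedTableError(f"design table must have columns {sorted(expected)}")
    return df


def write_experiment_set(experiments: ExperimentSet, directory: str | Path) -> list[Path]:
    """Per-experiment expression TSVs plus a single design table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    designs = {}
    for exp in experiments:
        p = directory / f"expression_{exp.id}.tsv"
        write_expression(exp.expression, p)
        written.append(p)
        designs[exp.id] = exp.design
    dp = directory / "design.tsv"
    write_design(designs, dp)
    written.append(dp)
    return written


def read_experiment_set(directory: str | Path) -> ExperimentSet:
    directory = Path(directory)
    design = read_design(directory / "design.tsv")
    experiments = []
    for exp_id, sub in design.groupby("experiment", sort=True):
        expr = read_expression(directory / f"expression_{exp_id}.tsv")
        experiments.append(Experiment(
            str(exp_id), expr, pd.Series(sub["condition"].to_numpy(),
                                         index=sub["sample"].to_numpy())))
    return ExperimentSet(experiments)


def write_gmt(term_to_genes: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term in sorted(term_to_genes):
            desc = (descriptions or {}).get(term, term)
            genes = "\t".join(sorted(term_to_genes[term]))
            fh.write(f"{term}\t{desc}\t{genes}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedTableError(f"GMT row {lineno}: expected >= 3 fields")
            out[parts[0]] = set(parts[2:])
    return out


def annotations_to_term_map(annotations: dict[str, set[str]]) -> dict[str, set[str]]:
    t2g: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        for t in terms:
            t2g.setdefault(t, set()).add(gene)
    return t2g


def term_map_to_annotations(term_to_genes: dict[str, set[str]]) -> dict[str, set[str]]:
    g2t: dict[str, set[str]] = {}
    for term, genes in term_to_genes.items():
        for g in genes:
            g2t.setdefault(g, set()).add(term)
    return g2t


def _checked_read(path: str | Path, columns: list[str]) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != columns:
            raise MalformedTableError(
                f"{path}: expected columns {columns}, found {header}")
        n = len(columns)
        for lineno, line in enumerate(fh, start=2):
            if line.strip() and len(line.rstrip("\n").split("\t")) != n:
                raise MalformedTableError(f"{path} row {lineno}: expected {n} fields")
    return pd.read_csv(path, sep="\t")


def write_dag_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges[["child", "parent"]].to_csv(path, sep="\t", index=False)


def read_dag_edges(path: str | Path) -> pd.DataFrame:
    return _checked_read(path, ["child", "parent"])


def write_similarity(similarity: pd.DataFrame, path: str | Path) -> None:
    similarity[["gene_a", "gene_b", "score"]].to_csv(path, sep="\t", index=False)


def read_similarity(path: str | Path) -> pd.DataFrame:
    return _checked_read(path, ["gene_a", "gene_b", "score"])


def write_motifs(motif_table: pd.DataFrame, path: str | Path) -> None:
    """Wide boolean gene x motif table -> long (gene, motif, count) TSV."""
    long = motif_table.stack()
    long = long[long.astype(bool)]
    df = long.reset_index()
    df.columns = ["gene", "motif", "count"]
    df["count"] = 1
    df.to_csv(path, sep="\t", index=False)


def read_motifs(path: str | Path, genes: list[str] | None = None) -> pd.DataFrame:
    long = _checked_read(path, ["gene", "motif", "count"])
    wide = (long.assign(present=long["count"] > 0)
            .pivot_table(index="gene", columns="motif", values="present",
                         aggfunc="any", fill_value=False))
    if genes is not None:
        wide = wide.reindex(genes, fill_value=False)
    return wide.astype(bool)


def write_gene_list(genes, path: str | Path) -> None:
    pd.Series(sorted(genes), name="gene").to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> set[str]:
    return set(pd.read_csv(path, sep="\t")["gene"].astype(str))


def write_sif(edges: pd.DataFrame, path: str | Path,
              interaction: str = "to") -> None:
    """SIF edge list: source <tab> interaction <tab> target."""
    with open(path, "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row.iloc[0]}\t{interaction}\t{row.iloc[1]}\n")


def write_graphml(edges: pd.DataFrame, path: str | Path,
                  module_of: pd.Series | None = None) -> None:
    g = nx.Graph()
    if module_of is not None:
        for gene, m in module_of.items():
            g.add_node(gene, module=int(m))
    for _, row in edges.iterrows():
        g.add_edge(row.iloc[0], row.iloc[1], to=float(row["to"]))
    nx.write_graphml(g, path)
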