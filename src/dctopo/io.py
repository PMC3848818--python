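"""Readers, writers, probe collapsing, network export and run configuration.

Expression input is delimited text (TSV by default): first column gene
id, header row of sample ids, body of log2 values. Labels are a
two-column file mapping sample id to group; the two groups are assigned
to conditions A and B in alphabetical order of the group name. Every
output table starts with provenance comment lines (package version,
config hash, seed) so that identical runs produce identical files.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .corrnet import ConditionPair, ExpressionMatrix, FisherZMatrix, fisher_transform

__all__ = [
    "RunConfig",
    "read_expression_table",
    "read_labels",
    "read_expression",
    "write_expression",
    "write_table",
    "read_table",
    "collapse_probes",
    "export_network",
]

_VERSION = "0.1.0"


@dataclass
class RunConfig:
    """Run parameters shared by the CLI subcommands.

    ``p_cutoff``/``d_cutoff`` are the detection thresholds for the
    global (p < S) and local (d > s) score; ``b_subsamples`` is the
    number of null subsample pairs for FDR estimation. All randomness
    flows from the single ``seed``.
    """

    method: str = "dcloc"
    k_thresholds: int | None = None  # None = per-method default (200/100)
    z_max: float | None = None  # None = from the data
    p_cutoff: float = 0.1
    d_cutoff: float = 0.25
    b_subsamples: int = 100
    seed: int = 0
    allow_unequal: bool = False
    absolute_correlation: bool = False
    sep: str = "\t"
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance_lines(config: RunConfig | None) -> list[str]:
    lines = [f"# dctopo {_VERSION}"]
    if config is not None:
        lines.append(f"# config_hash={config.config_hash()} seed={config.seed}")
        lines.append(f"# config={json.dumps(config.to_dict(), sort_keys=True)}")
    return lines


def read_expression_table(path, sep: str = "\t") -> ExpressionMatrix:
    """Read a genes x samples expression table (first column = gene id)."""
    frame = pd.read_csv(path, sep=sep, index_col=0, comment="#", float_precision="round_trip")
    if frame.empty:
        raise ValueError(f"empty expression table: {path}")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from None
    return ExpressionMatrix(
        tuple(map(str, frame.index)), tuple(map(str, frame.columns)), values
    )


def read_labels(path, sep: str = "\t") -> pd.Series:
    """Read a two-column sample -> group file (no header)."""
    frame = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if frame.shape[1] != 2:
        raise ValueError(f"label file must have exactly two columns: {path}")
    labels = pd.Series(frame[1].values, index=frame[0].values)
    if labels.index.has_duplicates:
        dups = labels.index[labels.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in label file: {dups[:5]}")
    return labels


def read_expression(
    path, label_path, sep: str = "\t", allow_unequal: bool = False
) -> ConditionPair:
    """Read an expression table plus labels and split into two conditions.

    The label file must define exactly two groups and cover every sample
    in the expression table; groups map to conditions A/B alphabetically.
    """
    em = read_expression_table(path, sep=sep)
    labels = read_labels(label_path, sep=sep)
    missing = [s for s in em.sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"sample(s) missing from label file: {missing[:5]}")
    labels = labels.loc[list(em.sample_ids)]
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    idx_a = np.flatnonzero((labels == groups[0]).to_numpy())
    idx_b = np.flatnonzero((labels == groups[1]).to_numpy())
    return ConditionPair(
        em.subset_samples(idx_a), em.subset_samples(idx_b), allow_unequal=allow_unequal
    )


def write_expression(
    em: ExpressionMatrix, path, sep: str = "\t", config: RunConfig | None = None
) -> None:
    """Write an expression matrix with a provenance header."""
    frame = pd.DataFrame(em.values, index=list(em.gene_ids), columns=list(em.sample_ids))
    frame.index.name = "gene_id"
    with open(path, "w") as fh:
        for line in _provenance_lines(config):
            fh.write(line + "\n")
        frame.to_csv(fh, sep=sep, float_format="%.17g")  # bitwise round-trip


def write_table(frame: pd.DataFrame, path, sep: str = "\t", config: RunConfig | None = None) -> None:
    """Write a result table with a provenance header."""
    with open(path, "w") as fh:
        for line in _provenance_lines(config):
            fh.write(line + "\n")
        frame.to_csv(fh, sep=sep, index=False)


def read_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep=sep, comment="#")


def collapse_probes(em: ExpressionMatrix, probe_to_gene: dict) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    For genes measured by several probes the probe with the highest mean
    expression across all samples is kept (ties go to the
    lexicographically smallest probe id). The map must cover every probe.
    """
    uncovered = [p for p in em.gene_ids if p not in probe_to_gene]
    if uncovered:
        raise ValueError(f"probe(s) missing from the map: {uncovered[:5]}")
    means = em.values.mean(axis=1)
    best: dict[str, tuple[float, str, int]] = {}
    for i, probe in enumerate(em.gene_ids):
        gene = str(probe_to_gene[probe])
        if not gene:
            raise ValueError(f"empty gene id for probe {probe}")
        cand = (-means[i], probe, i)  # max mean, then smallest probe id
        if gene not in best or cand < best[gene]:
            best[gene] = cand
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    return ExpressionMatrix(tuple(genes), em.sample_ids, em.values[rows])


def export_network(
    zmat: FisherZMatrix,
    pearson_threshold: float,
    path,
    fmt: str = "sif",
) -> None:
    """Export the thresholded network for external viewers (e.g. Cytoscape).

    ``pearson_threshold`` is given on the Pearson scale and converted to
    Fisher z internally. Formats: ``sif`` (edge list; isolated nodes as
    single-column lines) or ``graphml``. Node degree is attached as a
    node attribute in GraphML output.
    """
    if not (0 < pearson_threshold < 1):
        raise ValueError("Pearson threshold must lie in (0, 1)")
    t = fisher_transform(pearson_threshold)
    adj = zmat.z > t
    np.fill_diagonal(adj, False)
    graph = nx.Graph()
    graph.add_nodes_from(zmat.gene_ids)
    ii, jj = np.nonzero(np.triu(adj, 1))
    graph.add_edges_from(
        (zmat.gene_ids[i], zmat.gene_ids[j]) for i, j in zip(ii, jj)
    )
    nx.set_node_attributes(graph, dict(graph.degree()), "degree")
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for node in graph.nodes:
                neighbors = sorted(n for n in graph.neighbors(node) if n > node)
                if neighbors:
                    fh.write("\t".join([node, "cc"] + neighbors) + "\n")
                elif graph.degree(node) == 0:
                    fh.write(node + "\n")
    else:
        raise ValueError(f"unknown network format {fmt!r} (expected 'sif' or 'graphml')")
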