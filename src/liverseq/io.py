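"""Reading and writing the pipeline's on-disk formats.

Counts travel as TSV (gene rows, sample columns) or MatrixMarket with
plain-text row/column sidecars; metadata and results as TSV; simulation
truth as YAML; ontologies as a (child, parent) edge TSV plus an annotation
TSV, or a minimal OBO subset (id / name / is_a) via obonet.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .datatypes import CountMatrix
from .simulate import SimulationTruth

FLOAT_FMT = "%.10g"


def write_counts_tsv(cm: CountMatrix, counts_path, meta_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    cm.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_counts_tsv(counts_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    return CountMatrix(counts.astype(np.int64), meta)


def write_counts_mtx(cm: CountMatrix, mtx_path, meta_path) -> None:
    """MatrixMarket counts with ``.genes.txt`` / ``.samples.txt`` sidecars."""
    mtx_path = Path(mtx_path)
    mmwrite(str(mtx_path), csr_matrix(cm.counts.to_numpy()))
    mtx_path.with_suffix(".genes.txt").write_text("\n".join(cm.genes) + "\n")
    mtx_path.with_suffix(".samples.txt").write_text("\n".join(cm.samples) + "\n")
    cm.meta.to_csv(meta_path, sep="\t", index_label="sample_id")


def read_counts_mtx(mtx_path, meta_path) -> CountMatrix:
    mtx_path = Path(mtx_path)
    mat = np.asarray(mmread(str(mtx_path)).todense()).astype(np.int64)
    genes = mtx_path.with_suffix(".genes.txt").read_text().splitlines()
    samples = mtx_path.with_suffix(".samples.txt").read_text().splitlines()
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    return CountMatrix(counts, meta.loc[samples])


def write_truth_yaml(truth: SimulationTruth, path) -> None:
    Path(path).write_text(yaml.safe_dump(truth.to_dict(), sort_keys=True))


def read_truth_yaml(path) -> SimulationTruth:
    return SimulationTruth.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# ontology


def write_ontology_tsv(graph: nx.DiGraph, edges_path, annotations: pd.DataFrame | None = None,
                       annotations_path=None) -> None:
    rows = [{"child": c, "parent": p} for c, p in sorted(graph.edges)]
    pd.DataFrame(rows, columns=["child", "parent"]).to_csv(edges_path, sep="\t", index=False)
    if annotations is not None:
        annotations.to_csv(annotations_path, sep="\t", index=False)


def read_ontology_tsv(edges_path, annotations_path=None):
    edges = pd.read_csv(edges_path, sep="\t")
    g = nx.DiGraph()
    for _, row in edges.iterrows():
        g.add_edge(str(row["child"]), str(row["parent"]))
    ann = None
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", dtype=str)
    return g, ann


def read_obo(path) -> nx.DiGraph:
    """Minimal OBO reader: terms, names and is_a edges (child -> parent)."""
    net = obonet.read_obo(path)
    g = nx.DiGraph()
    for node, data in net.nodes(data=True):
        g.add_node(node, name=data.get("name", node))
    for child, parent, key in net.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return g


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Deterministic TSV output used by workflow stages (stable float format)."""
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
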