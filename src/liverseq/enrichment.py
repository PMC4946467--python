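"""Hypergeometric term enrichment over an ontology DAG.

Terms form a rooted DAG with child -> parent edges (is_a).  Annotations
obey the true-path rule: a gene annotated to a term counts for every
ancestor.  Each term is tested with a one-sided upper-tail hypergeometric
test of the study set against the universe; terms with fewer than five
observed study genes are removed before Benjamini-Hochberg adjustment,
and reporting keeps only "leaf" terms — significant terms with no
significant descendant.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust


def roots(dag: nx.DiGraph) -> list:
    return [n for n in dag.nodes if dag.out_degree(n) == 0]


def propagate_annotations(dag: nx.DiGraph, direct: dict) -> dict:
    """True-path propagation: each term's gene set is its direct
    annotations plus those of all its descendants (terms below it)."""
    try:
        order = list(nx.topological_sort(dag))  # children before parents
    except nx.NetworkXUnfeasible as err:
        raise ValueError("ontology graph contains a cycle") from err
    out: dict = {}
    for term in order:
        genes = set(direct.get(term, ()))
        for child in dag.predecessors(term):
            genes |= out[child]
        out[term] = genes
    return out


def annotation_table_to_direct(ann: pd.DataFrame) -> dict:
    direct: dict = {}
    for gene, term in ann[["gene", "term"]].itertuples(index=False):
        direct.setdefault(term, set()).add(gene)
    return direct


def hypergeom_enrich(dag: nx.DiGraph, direct: dict, study, universe,
                     min_observed: int = 5,
                     filter_before_adjust: bool = True,
                     study_as_universe: bool = False) -> pd.DataFrame:
    """Per-term upper-tail hypergeometric enrichment of ``study`` in ``universe``.

    ``study_as_universe`` reproduces a literal "reference set = DE genes"
    reading (degenerate: every p becomes 1); the default universe should be
    the expression-filtered gene list.  When ``filter_before_adjust``,
    terms with ``k < min_observed`` are dropped before BH; otherwise BH
    runs first and the filter applies afterwards.
    """
    study = set(study)
    universe = set(study) if study_as_universe else set(universe)
    if not study <= universe:
        raise ValueError("study set must be contained in the universe")
    if not study:
        warnings.warn("empty study set; returning empty enrichment table", stacklevel=2)
        return pd.DataFrame(columns=["name", "N", "K", "n", "k", "p", "q"])

    propagated = propagate_annotations(dag, direct)
    N, n = len(universe), len(study)
    rows = []
    for term in dag.nodes:
        term_genes = propagated[term] & universe
        K = len(term_genes)
        k = len(term_genes & study)
        if K == 0:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, dag.nodes[term].get("name", term), N, K, n, k, p))
    table = pd.DataFrame(rows, columns=["term", "name", "N", "K", "n", "k", "p"])
    table = table.set_index("term")
    if filter_before_adjust:
        table = table[table["k"] >= min_observed].copy()
        table["q"] = bh_adjust(table["p"].to_numpy())
    else:
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table[table["k"] >= min_observed].copy()
    return table.sort_values("p")


def leaf_filter(results: pd.DataFrame, dag: nx.DiGraph,
                fdr_threshold: float = 0.001) -> pd.DataFrame:
    """Keep significant terms that have no significant descendant.

    A term is significant when ``q < fdr_threshold``.  The returned subset
    carries a boolean ``leaf`` column (always True) so written tables are
    self-describing.
    """
    sig = set(results.index[results["q"] < fdr_threshold])
    reported = []
    for term in results.index:
        if term not in sig:
            continue
        descendants = nx.ancestors(dag, term)  # edges child->parent
        if not (descendants & sig):
            reported.append(term)
    out = results.loc[reported].copy()
    out["leaf"] = True
    return out
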