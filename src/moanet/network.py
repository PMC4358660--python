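"""Cell-state-specific weighted interaction networks.

A generic protein–protein interaction network is intersected with the set
of expressed genes (FPKM above a floor in either condition), and each
surviving edge is weighted by the transcriptional co-regulation of its two
endpoints upon drug treatment.  Edges between two regulated proteins are
up-weighted; an edge with at least one unregulated endpoint keeps the
baseline weight of 1.  The weighted network defines a column-stochastic
transition operator used by the diffusion module.
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: FPKM floor below which a gene counts as not expressed, and the
#: pseudocount added to both conditions when forming fold changes.
FPKM_MIN = 0.1

WeightFunction = Callable[[float, float], float]


def _weight_min(abs_lfc_a: float, abs_lfc_b: float) -> float:
    return 1.0 + min(abs_lfc_a, abs_lfc_b)


def _weight_geometric(abs_lfc_a: float, abs_lfc_b: float) -> float:
    return 1.0 + float(np.sqrt(abs_lfc_a * abs_lfc_b))


WEIGHT_FUNCTIONS: dict[str, WeightFunction] = {
    "min_abs_log2": _weight_min,
    "geometric_abs_log2": _weight_geometric,
}


def clean_network(graph: nx.Graph) -> nx.Graph:
    """Return a simple undirected copy: self-loops dropped, duplicates collapsed."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    g.add_edges_from((e[0], e[1]) for e in graph.edges if e[0] != e[1])
    return g


def fold_changes(profile: pd.DataFrame, pseudocount: float = FPKM_MIN) -> pd.Series:
    """Per-gene fold change (treated / control) with a pseudocount on both sides.

    If the profile already carries a ``fold_change`` column it takes
    precedence over the FPKM columns.
    """
    if "fold_change" in profile.columns:
        fc = profile["fold_change"].astype(float)
    else:
        fc = (profile["fpkm_treated"] + pseudocount) / (
            profile["fpkm_control"] + pseudocount
        )
    if (fc <= 0).any():
        bad = fc.index[fc <= 0].tolist()[:5]
        raise ValueError(f"non-positive fold changes for genes {bad}")
    return fc


def filter_expressed(
    graph: nx.Graph, profile: pd.DataFrame, fpkm_min: float = FPKM_MIN
) -> nx.Graph:
    """Induced subgraph on genes expressed (FPKM > ``fpkm_min``) in either condition.

    Genes absent from the profile count as not expressed.  Nodes left
    isolated after the intersection are dropped so the transition operator
    stays well defined.

    Raises
    ------
    ValueError
        If no edge survives the intersection (diffusion would be undefined).
    """
    expressed = set(
        profile.index[
            (profile["fpkm_control"] > fpkm_min) | (profile["fpkm_treated"] > fpkm_min)
        ]
    )
    kept = [n for n in graph.nodes if n in expressed]
    sub = nx.Graph(graph.subgraph(kept))
    sub.remove_nodes_from([n for n, d in dict(sub.degree()).items() if d == 0])
    if sub.number_of_edges() == 0:
        raise ValueError("expression filter removed every edge; no network left")
    logger.info(
        "expression filter: %d/%d nodes, %d/%d edges kept",
        sub.number_of_nodes(),
        graph.number_of_nodes(),
        sub.number_of_edges(),
        graph.number_of_edges(),
    )
    return sub


def weight_edges(
    graph: nx.Graph,
    fold_change: Mapping[str, float] | pd.Series,
    weight_function: str = "min_abs_log2",
) -> nx.Graph:
    """Attach co-regulation weights ``w_AB = 1 + f(|log2 fC_A|, |log2 fC_B|)``.

    The default combiner ``f`` is the minimum of the two absolute log2 fold
    changes, so an edge with one unregulated endpoint keeps weight 1 and an
    edge between two co-regulated proteins is up-weighted regardless of the
    direction of regulation.  Genes without a fold change count as
    unregulated (fC = 1).
    """
    try:
        combine = WEIGHT_FUNCTIONS[weight_function]
    except KeyError:
        raise ValueError(
            f"unknown weight function {weight_function!r}; "
            f"choices: {sorted(WEIGHT_FUNCTIONS)}"
        ) from None
    abs_lfc: dict[str, float] = {}
    for node in graph.nodes:
        fc = float(fold_change.get(node, 1.0))
        if fc <= 0:
            raise ValueError(f"fold change must be positive, got {fc} for {node!r}")
        abs_lfc[node] = abs(np.log2(fc))
    wnet = nx.Graph()
    wnet.add_nodes_from(graph.nodes)
    for a, b in graph.edges:
        wnet.add_edge(a, b, weight=combine(abs_lfc[a], abs_lfc[b]))
    return wnet


def transition_operator(wnet: nx.Graph) -> tuple[sp.csr_matrix, list]:
    """Column-stochastic transition matrix of the weighted network.

    Entry (B, A) is ``w_AB / sum_C w_AC``: the probability that a walker at
    A steps to B.  Every node must have degree >= 1.

    Returns the sparse operator and the node order its rows/columns follow.
    """
    nodes = list(wnet.nodes)
    degrees = dict(wnet.degree())
    isolated = [n for n in nodes if degrees[n] == 0]
    if isolated:
        raise ValueError(f"isolated nodes have no transition column: {isolated[:5]}")
    adj = nx.to_scipy_sparse_array(wnet, nodelist=nodes, weight="weight", format="csr")
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    operator = (adj @ sp.diags(1.0 / col_sums)).tocsr()
    return operator, nodes
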