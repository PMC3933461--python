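"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from expmods.containers import CASE, CONTROL, ExpressionMatrix
from expmods.interactome import WeightedInteractome, weight_edges


def build_wnet(edges, t):
    """WeightedInteractome from an edge list and a t dict, via the package path."""
    g = nx.Graph()
    g.add_edges_from(edges)
    g.add_nodes_from(t)
    return weight_edges(g, pd.Series(t))


def two_clique_graph(w_seed=0.9, w_other=0.1, w_bridge=0.1):
    """Two 6-cliques joined by one bridge edge; returns (graph, weights dict).

    Nodes a0..a5 form the heavy clique (the seed lives at a0), b0..b5 the
    light one; the bridge joins a5-b0.
    """
    g = nx.Graph()
    a = [f"a{i}" for i in range(6)]
    b = [f"b{i}" for i in range(6)]
    for grp, w in ((a, w_seed), (b, w_other)):
        for i in range(6):
            for j in range(i + 1, 6):
                g.add_edge(grp[i], grp[j], weight=w)
    g.add_edge("a5", "b0", weight=w_bridge)
    return g


def wnet_from_weighted_graph(g, t=None):
    """Wrap a graph that already carries explicit edge weights."""
    if t is None:
        t = pd.Series(1.0, index=list(g.nodes))
    return WeightedInteractome(graph=g, t=pd.Series(t), t_max=float(pd.Series(t).abs().max()))


def expression_from_array(x, n_case, n_control, genes=None):
    x = np.asarray(x, dtype=float)
    genes = genes if genes is not None else [f"g{i}" for i in range(x.shape[0])]
    samples = [f"c{i}" for i in range(n_case)] + [f"k{i}" for i in range(n_control)]
    groups = pd.Series([CASE] * n_case + [CONTROL] * n_control, index=samples)
    return ExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples), groups)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
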