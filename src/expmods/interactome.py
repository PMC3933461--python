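"""Interactome input, integration with the array, and statistic edge weights.

The edge weight between interacting genes g and h is the normalized
combined strength of their differential-expression statistics,

    w_gh = (|t_g| + |t_h|) / (2 * t_max),

where t_max is the maximum absolute statistic over the network nodes, so
every weight lies in [0, 1] and w_gh = 1 exactly when both endpoints attain
t_max.  Non-interacting pairs carry no weight.  The displayed form of this
weighting is an average of the two endpoint |t| values rescaled by the
maximum; the normalization is pluggable for sensitivity analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedInteractome",
    "read_interactome",
    "integrate",
    "weight_edges",
    "write_weighted_edges",
]


@dataclass
class WeightedInteractome:
    """Undirected simple graph with statistic-derived edge weights.

    ``graph`` carries a ``weight`` attribute on every edge; ``t`` maps each
    node to its signed statistic; ``t_max`` is the normalization constant
    (max |t| over network nodes).
    """

    graph: nx.Graph
    t: pd.Series
    t_max: float

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    def edge_weight(self, g, h) -> float:
        return self.graph.edges[g, h]["weight"]

    def abs_t(self) -> pd.Series:
        return self.t.abs()


def _parse_lines(path: str | Path, fmt: str) -> Iterable[tuple[str, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fmt == "edge-list":
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
                yield fields[0], fields[1]
            elif fmt == "sif":
                # SIF: source <tab> interaction-type <tab> target [target ...]
                if len(fields) == 1:
                    yield fields[0], fields[0]  # lone node: recorded, no edge
                elif len(fields) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: SIF line needs source, type and >=1 target"
                    )
                else:
                    for target in fields[2:]:
                        yield fields[0], target
            else:
                raise ValueError(f"unknown interactome format {fmt!r}")


def read_interactome(path: str | Path, fmt: str = "edge-list") -> nx.Graph:
    """Read a simple undirected graph from an edge list or SIF file.

    Duplicate and reversed-duplicate lines collapse to one edge; self-loops
    are dropped with a logged count.  The SIF interaction-type column is
    ignored.
    """
    g = nx.Graph()
    n_self = 0
    for a, b in _parse_lines(path, fmt):
        if a == b:
            n_self += 1
            g.add_node(a)
        else:
            g.add_edge(a, b)
    if n_self:
        logger.info("dropped %d self-loop line(s) from %s", n_self, path)
    logger.info("read interactome %s: %d nodes, %d edges", path, g.number_of_nodes(),
                g.number_of_edges())
    return g


def integrate(graph: nx.Graph, measured_genes: Iterable) -> nx.Graph:
    """Induced subgraph on network nodes that were measured on the array.

    Isolated nodes are retained (flagged via a node attribute) so the
    caller can decide whether to keep them.  Node and edge counts are
    logged.
    """
    measured = set(measured_genes)
    keep = measured & set(graph.nodes)
    if not keep:
        raise ValueError("no overlap between the interactome and the measured genes")
    sub = graph.subgraph(keep).copy()
    for node in sub.nodes:
        sub.nodes[node]["isolated"] = sub.degree(node) == 0
    logger.info(
        "integrated network: %d proteins, %d interactions (from %d / %d)",
        sub.number_of_nodes(), sub.number_of_edges(),
        graph.number_of_nodes(), graph.number_of_edges(),
    )
    return sub


def _default_norm(abs_t_g: np.ndarray, abs_t_h: np.ndarray, t_max: float) -> np.ndarray:
    return (abs_t_g + abs_t_h) / (2.0 * t_max)


def weight_edges(
    graph: nx.Graph,
    stats: pd.DataFrame | pd.Series,
    t_max_scope: str = "network",
    norm: Callable[[np.ndarray, np.ndarray, float], np.ndarray] = _default_norm,
) -> WeightedInteractome:
    """Attach w_gh = (|t_g| + |t_h|) / (2 t_max) to every edge.

    ``stats`` is a DEStats table (column ``t`` used) or a Series of t per
    gene; every graph node must have a statistic.  ``t_max_scope`` selects
    whether t_max is the maximum |t| over network nodes (default) or over
    all genes in ``stats`` (``"all"``).
    """
    t = stats["t"] if isinstance(stats, pd.DataFrame) else pd.Series(stats)
    missing = [n for n in graph.nodes if n not in t.index]
    if missing:
        raise ValueError(f"{len(missing)} network node(s) lack a statistic, e.g. {missing[:5]}")
    t_net = t.loc[list(graph.nodes)].astype(float)
    if t_max_scope == "network":
        t_max = float(t_net.abs().max()) if len(t_net) else 0.0
    elif t_max_scope == "all":
        t_max = float(t.abs().max())
    else:
        raise ValueError("t_max_scope must be 'network' or 'all'")
    if not t_max > 0:
        raise ValueError("all statistics are zero; edge-weight normalization is degenerate")

    abs_t = t_net.abs()
    g = graph.copy()
    for a, b in g.edges:
        g.edges[a, b]["weight"] = float(norm(abs_t[a], abs_t[b], t_max))
    return WeightedInteractome(graph=g, t=t_net, t_max=t_max)


def write_weighted_edges(wnet: WeightedInteractome, path: str | Path) -> None:
    """Weighted edge list, tab-separated, 6 decimal places."""
    with open(path, "w") as fh:
        for a, b, w in wnet.graph.edges.data("weight"):
            fh.write(f"{a}\t{b}\t{w:.6f}\n")


def write_graphml(wnet: WeightedInteractome, path: str | Path) -> None:
    """GraphML export (node statistic + edge weight) for visualization tools."""
    g = wnet.graph.copy()
    for node in g.nodes:
        g.nodes[node]["t"] = float(wnet.t[node])
    nx.write_graphml(g, path)
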