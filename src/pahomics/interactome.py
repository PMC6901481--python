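"""Protein-protein interactome graph model and algorithms.

The interactome is an undirected simple graph of protein identifiers whose
edges carry sets of experimental-evidence codes. It supplies the shortest
path distances d(a, b) used by the network-proximity statistic and the
degree bins used to draw degree-preserving random node sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .omics_io import EVIDENCE_CODES, PREDICTED_CODE, OmicsIOError


class InteractomeError(ValueError):
    """Raised for invalid graph construction or queries."""


class Interactome:
    """Undirected simple graph of proteins with per-edge evidence codes."""

    def __init__(self, graph: nx.Graph):
        if any(u == v for u, v in graph.edges):
            raise InteractomeError("self-loops are not allowed")
        self._g = graph

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    def sorted_nodes(self) -> list[str]:
        return sorted(self._g.nodes)

    def degree(self, node: str) -> int:
        return self._g.degree[node]

    def degrees(self) -> dict[str, int]:
        return dict(self._g.degree())

    def evidence(self, a: str, b: str) -> frozenset[str]:
        return self._g.edges[a, b].get("evidence", frozenset())

    def has_node(self, node: str) -> bool:
        return self._g.has_node(node)

    def induced(self, nodes: Iterable[str]) -> "Interactome":
        return Interactome(self._g.subgraph(nodes).copy())

    def export_edges(self) -> pd.DataFrame:
        """One row per (edge, evidence code), deterministically ordered."""
        rows = []
        for u, v, data in self._g.edges(data=True):
            a, b = sorted((u, v))
            for code in sorted(data.get("evidence", frozenset())):
                rows.append((a, b, code))
        rows.sort()
        return pd.DataFrame(rows, columns=["node_a", "node_b", "evidence_code"])

    def adjacency(self) -> tuple[sp.csr_matrix, list[str]]:
        order = self.sorted_nodes()
        mat = nx.to_scipy_sparse_array(self._g, nodelist=order, format="csr")
        return mat, order


def build_interactome(edge_records, keep_evidence: Iterable[str] = EVIDENCE_CODES
                      ) -> Interactome:
    """Assemble an interactome from raw edge records.

    Edges whose evidence code is outside ``keep_evidence`` (notably the
    ``PRED`` computational predictions) and self-loops are dropped; duplicate
    undirected edges are merged with the union of their evidence codes.
    """
    keep = frozenset(keep_evidence)
    bad = keep - EVIDENCE_CODES
    if bad:
        raise OmicsIOError(f"unknown evidence codes in keep set: {sorted(bad)}")
    if isinstance(edge_records, pd.DataFrame):
        rows = edge_records[["node_a", "node_b", "evidence_code"]].itertuples(
            index=False)
    else:
        rows = edge_records
    g = nx.Graph()
    for a, b, code in rows:
        if code not in keep or a == b:
            continue
        a, b = str(a), str(b)
        if g.has_edge(a, b):
            g.edges[a, b]["evidence"] = g.edges[a, b]["evidence"] | {code}
        else:
            g.add_edge(a, b, evidence=frozenset({code}))
    if g.number_of_edges() == 0:
        raise InteractomeError("no edges survive evidence filtering")
    return Interactome(g)


def shortest_paths(net: Interactome, sources: Iterable[str]
                   ) -> dict[tuple[str, str], int]:
    """BFS hop distances from each source; unreachable pairs are absent."""
    out: dict[tuple[str, str], int] = {}
    for s in sources:
        if not net.has_node(s):
            raise InteractomeError(f"source {s!r} not in graph")
        for node, d in nx.single_source_shortest_path_length(net.graph, s).items():
            out[(s, node)] = d
    return out


def distance_matrix(net: Interactome) -> tuple[np.ndarray, dict[str, int]]:
    """All-pairs BFS hop distances as a dense array (inf = unreachable)."""
    adj, order = net.adjacency()
    dist = _csgraph_shortest_path(adj, method="D", unweighted=True,
                                  directed=False)
    return dist, {node: i for i, node in enumerate(order)}


def largest_connected_component(net: Interactome) -> Interactome:
    """Induced subgraph on the largest component.

    Ties on size are broken by the smallest lexicographic member node so the
    choice is deterministic.
    """
    comps = [sorted(c) for c in nx.connected_components(net.graph)]
    if not comps:
        raise InteractomeError("empty graph has no components")
    comps.sort(key=lambda c: (-len(c), c[0]))
    return net.induced(comps[0])


@dataclass
class DegreeBins:
    """Partition of nodes into contiguous-degree bins of a minimum size.

    ``bins`` is an ascending list of ((lo_degree, hi_degree), sorted nodes).
    Used to draw random node sets matching an observed set's degree
    distribution.
    """

    bins: list[tuple[tuple[int, int], list[str]]]
    min_bin_size: int

    def bin_of(self, degree: int) -> int:
        for i, ((lo, hi), _) in enumerate(self.bins):
            if lo <= degree <= hi:
                return i
        raise InteractomeError(f"degree {degree} outside all bins")

    def members(self, i: int) -> list[str]:
        return self.bins[i][1]

    def __len__(self) -> int:
        return len(self.bins)


def default_min_bin_size(n_nodes: int) -> int:
    """100 for full-scale graphs, max(5, n/50) for small synthetic ones."""
    return min(100, max(5, n_nodes // 50))


def make_degree_bins(net: Interactome, min_bin_size: int | None = None
                     ) -> DegreeBins:
    """Greedily merge ascending degree values until every bin holds at least
    ``min_bin_size`` nodes; a final undersized bin is merged into its
    predecessor."""
    if min_bin_size is None:
        min_bin_size = default_min_bin_size(net.n_nodes)
    if min_bin_size > net.n_nodes:
        raise InteractomeError(
            f"min_bin_size {min_bin_size} exceeds node count {net.n_nodes}")
    by_degree: dict[int, list[str]] = {}
    for node, deg in net.degrees().items():
        by_degree.setdefault(deg, []).append(node)
    bins: list[tuple[tuple[int, int], list[str]]] = []
    cur_nodes: list[str] = []
    cur_lo: int | None = None
    for deg in sorted(by_degree):
        if cur_lo is None:
            cur_lo = deg
        cur_nodes.extend(by_degree[deg])
        if len(cur_nodes) >= min_bin_size:
            bins.append(((cur_lo, deg), sorted(cur_nodes)))
            cur_nodes, cur_lo = [], None
    if cur_nodes:
        if bins:
            (lo, _), prev = bins.pop()
            bins.append(((lo, max(by_degree)), sorted(prev + cur_nodes)))
        else:
            bins.append(((cur_lo, max(by_degree)), sorted(cur_nodes)))
    return DegreeBins(bins=bins, min_bin_size=min_bin_size)
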