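"""Protein–protein interaction networks.

Builds the merged interactome used for all distance computations: scored
edge tables (STRING-dialect, ``combined_score`` in [0, 1]) are filtered at
a confidence cutoff, unscored lists are taken as-is, and all sources are
unioned into one undirected simple graph with per-edge source tags.
Shortest paths are unweighted hop counts.
"""

from __future__ import annotations

import math
from collections import deque
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import InvalidParameterError, ParseError

__all__ = [
    "UNREACHABLE",
    "InteractionNetwork",
    "filter_scored_edges",
    "merge_networks",
    "induced_subnetwork",
    "read_edge_table",
    "write_edge_table",
    "write_sif",
]

#: Sentinel returned by :meth:`InteractionNetwork.shortest_path_length`
#: when two nodes are disconnected or absent.
UNREACHABLE = math.inf


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class InteractionNetwork:
    """Undirected simple graph of gene symbols.

    Thin wrapper around :class:`networkx.Graph` guaranteeing no self-loops
    and carrying per-edge source tags under the ``sources`` edge attribute.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = nx.Graph()
        if graph is not None:
            for n in graph.nodes:
                self.graph.add_node(n)
            for a, b, data in graph.edges(data=True):
                if a == b:
                    continue
                self.graph.add_edge(a, b, **data)

    # -- basic container protocol ------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_canonical_edge(a, b) for a, b in self.graph.edges}

    @property
    def source_tags(self) -> dict[tuple[str, str], set[str]]:
        return {
            _canonical_edge(a, b): set(data.get("sources", set()))
            for a, b, data in self.graph.edges(data=True)
        }

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    # -- distance primitives -----------------------------------------
    def degree(self, gene: str) -> int:
        """Number of distinct neighbors; 0 for genes absent from the network."""
        if gene not in self.graph:
            return 0
        return self.graph.degree(gene)

    def shortest_path_length(self, g: str, t: str) -> float:
        """Unweighted hop count between ``g`` and ``t``.

        Returns 0 when ``g == t`` (and the node exists), and
        :data:`UNREACHABLE` when either node is absent or no path exists.
        """
        if g not in self.graph or t not in self.graph:
            return UNREACHABLE
        if g == t:
            return 0
        try:
            return nx.shortest_path_length(self.graph, g, t)
        except nx.NetworkXNoPath:
            return UNREACHABLE

    def multi_source_distances(self, sources: Iterable[str]) -> dict[str, float]:
        """Hop distance from every node to its nearest node in ``sources``.

        One breadth-first search seeded from all present sources; nodes
        unreachable from every source get :data:`UNREACHABLE`.
        """
        dist: dict[str, float] = {n: UNREACHABLE for n in self.graph.nodes}
        queue: deque[str] = deque()
        for s in sources:
            if s in self.graph:
                dist[s] = 0
                queue.append(s)
        while queue:
            u = queue.popleft()
            for v in self.graph[u]:
                if dist[v] == UNREACHABLE:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        return dist


def filter_scored_edges(
    table: pd.DataFrame | Sequence[tuple], min_score: float
) -> list[tuple[str, str, float]]:
    """Retain rows with ``combined_score >= min_score``; drop self-rows.

    The boundary is inclusive: a row scoring exactly at the cutoff is
    retained.  Accepts a DataFrame with columns
    ``protein1/protein2/combined_score`` or an iterable of
    ``(a, b, score)`` tuples.

    Raises
    ------
    ParseError
        If any score lies outside [0, 1] (the offending row is named).
    InvalidParameterError
        If ``min_score`` is outside [0, 1].
    """
    if not 0.0 <= min_score <= 1.0:
        raise InvalidParameterError(f"min_score must be in [0, 1], got {min_score}")
    if isinstance(table, pd.DataFrame):
        rows = list(
            zip(table["protein1"], table["protein2"], table["combined_score"])
        )
    else:
        rows = [tuple(r) for r in table]
    out: list[tuple[str, str, float]] = []
    for i, (a, b, score) in enumerate(rows):
        score = float(score)
        if not 0.0 <= score <= 1.0:
            raise ParseError(
                f"row {i} ({a}, {b}): combined_score {score} outside [0, 1]"
            )
        if a == b:
            continue
        if score >= min_score:
            out.append((a, b, score))
    return out


def merge_networks(
    edge_lists: Mapping[str, Iterable[tuple[Hashable, ...]]]
) -> InteractionNetwork:
    """Union named edge lists into one undirected network.

    Edges are deduplicated orientation-invariantly; self-loops are
    dropped; ``sources`` edge tags record every contributing list.  Tuples
    may carry extra columns (e.g. a score), which are ignored here.
    """
    net = InteractionNetwork()
    g = net.graph
    for source in edge_lists:
        for row in edge_lists[source]:
            a, b = str(row[0]), str(row[1])
            if a == b:
                continue
            if g.has_edge(a, b):
                g[a][b]["sources"].add(source)
            else:
                g.add_edge(a, b, sources={source})
    return net


def induced_subnetwork(
    network: InteractionNetwork, gene_set: Iterable[str]
) -> tuple[InteractionNetwork, tuple[int, int]]:
    """Subgraph on ``gene_set``, with isolated nodes removed.

    Returns the subnetwork and its ``(n_nodes, n_edges)``.  Nodes of the
    subgraph with degree zero are dropped, so every retained node takes
    part in at least one retained interaction.
    """
    keep = set(gene_set) & network.nodes
    sub = network.graph.subgraph(keep).copy()
    isolated = [n for n in sub.nodes if sub.degree(n) == 0]
    sub.remove_nodes_from(isolated)
    out = InteractionNetwork(sub)
    return out, (out.number_of_nodes(), out.number_of_edges())


# ---------------------------------------------------------------------------
# I/O


def read_edge_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV edge list with header ``protein1 protein2 [combined_score]``.

    The score column is optional (PINA/HuRI-style unscored lists); when
    absent, a ``combined_score`` column of 1.0 is added so downstream
    filtering is a no-op.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = list(df.columns)
    if len(cols) < 2:
        raise ParseError(f"{path}: expected at least two columns, got {cols}")
    df = df.rename(columns={cols[0]: "protein1", cols[1]: "protein2"})
    if "combined_score" not in df.columns:
        df["combined_score"] = 1.0
    return df[["protein1", "protein2", "combined_score"]]


def write_edge_table(network: InteractionNetwork, path: str | Path) -> None:
    """Write the merged network as TSV with a ``sources`` column."""
    tags = network.source_tags
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tsources\n")
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\t{','.join(sorted(tags.get((a, b), set())))}\n")


def write_sif(network: InteractionNetwork, path: str | Path,
              relation: str = "pp") -> None:
    """Write a SIF file for visualization tools (one edge per row)."""
    with open(path, "w") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{relation}\t{b}\n")
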