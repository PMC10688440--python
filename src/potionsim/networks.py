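"""Network architectures and statistics.

Generators for the idealized topologies the model is studied on
(connectedness-conditioned Erdős–Rényi, rings, complete graphs, connected
caveman), a loader for real-world edge lists (optionally weighted), and the
summary statistics reported for them.  All graphs are undirected
``networkx.Graph`` objects; node labels are 0..N-1, with the original
labels of loaded edge lists kept in ``G.graph["label_map"]``.
"""

from __future__ import annotations

import csv
import random
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

__all__ = [
    "NetworkStats",
    "make_random_network",
    "make_ring",
    "make_complete",
    "make_connected_caveman",
    "load_edge_list",
    "network_stats",
]


@dataclass(frozen=True)
class NetworkStats:
    """Summary statistics of a connected network.

    Path length and clustering are computed on the unweighted topology even
    for weighted networks.  Both the plain average degree and (when edge
    weights are present) the weighted average degree — the mean sum of
    incident edge weights — are reported, since field usage of
    "connectivity" is ambiguous between the two.
    """

    n: int
    avg_path_length: float
    avg_degree: float
    avg_weighted_degree: float | None
    clustering: float
    density: float
    is_complete: bool


def _as_rng(seed) -> random.Random:
    return seed if isinstance(seed, random.Random) else random.Random(seed)


def make_random_network(
    n: int, p: float, seed=None, max_attempts: int = 10_000
) -> nx.Graph:
    """Erdős–Rényi G(n, p) conditioned on connectedness.

    Draws are rejected until a connected graph appears (at most
    ``max_attempts``); ``p = 1`` deterministically yields the complete
    graph.  Every agent in the model needs at least one partner, hence the
    conditioning.
    """
    if n < 2:
        raise ValueError("make_random_network needs n >= 2")
    if not 0 < p <= 1:
        raise ValueError("edge probability p must be in (0, 1]")
    if p == 1:
        return make_complete(n)
    rng = _as_rng(seed)
    for _ in range(max_attempts):
        g = nx.gnp_random_graph(n, p, seed=rng)
        if nx.is_connected(g):
            g.graph["weighted"] = False
            return g
    raise RuntimeError(
        f"no connected G(n={n}, p={p}) draw in {max_attempts} attempts; "
        "increase p or the attempt budget"
    )


def make_ring(n: int) -> nx.Graph:
    """Cycle graph on ``n`` >= 3 nodes (every node has degree 2)."""
    if n < 3:
        raise ValueError("make_ring needs n >= 3")
    g = nx.cycle_graph(n)
    g.graph["weighted"] = False
    return g


def make_complete(n: int) -> nx.Graph:
    """Complete graph on ``n`` >= 2 nodes."""
    if n < 2:
        raise ValueError("make_complete needs n >= 2")
    g = nx.complete_graph(n)
    g.graph["weighted"] = False
    return g


def make_connected_caveman(num_cliques: int, clique_size: int) -> nx.Graph:
    """Connected caveman graph: cliques on a ring, one edge per clique rewired.

    For ``clique_size >= 3`` this is the standard construction (one
    within-clique edge removed and one link to the neighbouring clique
    added, so the edge count stays ``num_cliques * C(clique_size, 2)``).
    For ``clique_size == 2`` removing the only within-clique edge would
    isolate a node, so the edge is kept and only the inter-clique link is
    added, yielding a connected cycle-of-dyads.
    """
    if num_cliques < 2:
        raise ValueError("make_connected_caveman needs num_cliques >= 2")
    if clique_size < 2:
        raise ValueError("make_connected_caveman needs clique_size >= 2")
    if clique_size == 2:
        g = nx.caveman_graph(num_cliques, 2)
        total = 2 * num_cliques
        for start in range(0, total, 2):
            g.add_edge(start, (start - 1) % total)
    else:
        g = nx.connected_caveman_graph(num_cliques, clique_size)
    assert nx.is_connected(g)
    g.graph["weighted"] = False
    return g


def load_edge_list(path: str | Path, weighted: bool = False) -> nx.Graph:
    """Load an undirected network from a ``source,target[,weight]`` file.

    Comma- or tab-separated; a header row is auto-detected.  Self-loop rows
    are dropped with a warning; duplicate rows are collapsed (weights
    summed, with a warning).  Node labels are mapped to 0..N-1 in
    lexicographic order of the original labels; the mapping is stored in
    ``G.graph["label_map"]``.
    """
    path = Path(path)
    rows: list[tuple[str, str, float]] = []
    with open(path, newline="") as fh:
        text = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    if not text:
        raise ValueError(f"{path}: empty edge list")
    delim = "\t" if "\t" in text[0] else ","
    for lineno, line in enumerate(text, start=1):
        parts = [p.strip() for p in next(csv.reader([line], delimiter=delim))]
        if lineno == 1 and _looks_like_header(parts):
            continue
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}:{lineno}: expected 2 or 3 fields, got {len(parts)}")
        w = 1.0
        if weighted and len(parts) == 3:
            w = float(parts[2])
            if w <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive weight {w}")
        if parts[0] == parts[1]:
            warnings.warn(f"{path}:{lineno}: dropping self-loop on {parts[0]!r}")
            continue
        rows.append((parts[0], parts[1], w))
    if not rows:
        raise ValueError(f"{path}: no edges after filtering")

    labels = sorted({u for u, _, _ in rows} | {v for _, v, _ in rows})
    index = {lbl: i for i, lbl in enumerate(labels)}
    g = nx.Graph()
    g.add_nodes_from(range(len(labels)))
    for u, v, w in rows:
        i, j = index[u], index[v]
        if g.has_edge(i, j):
            warnings.warn(f"{path}: duplicate edge {u!r}-{v!r} collapsed")
            if weighted:
                g[i][j]["weight"] += w
        else:
            g.add_edge(i, j, **({"weight": w} if weighted else {}))
    g.graph["weighted"] = weighted
    g.graph["label_map"] = index
    return g


def _looks_like_header(parts: list[str]) -> bool:
    if len(parts) < 2:
        return False
    head = {p.lower() for p in parts[:2]}
    return bool(head & {"source", "target", "from", "to", "node1", "node2"})


def network_stats(net: nx.Graph) -> NetworkStats:
    """Summary statistics; raises on disconnected input (path length undefined)."""
    if net.number_of_nodes() < 2:
        raise ValueError("network_stats needs at least 2 nodes")
    if not nx.is_connected(net):
        raise ValueError("network is disconnected: average path length undefined")
    n = net.number_of_nodes()
    weighted = any("weight" in d for _, _, d in net.edges(data=True))
    avg_wdeg = None
    if weighted:
        avg_wdeg = sum(d for _, d in net.degree(weight="weight")) / n
    return NetworkStats(
        n=n,
        avg_path_length=nx.average_shortest_path_length(net),
        avg_degree=sum(d for _, d in net.degree()) / n,
        avg_weighted_degree=avg_wdeg,
        clustering=nx.average_clustering(net),
        density=nx.density(net),
        is_complete=nx.density(net) == 1.0,
    )
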