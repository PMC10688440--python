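"""Inequality and centrality measures.

The inequality index is the Gini coefficient over per-agent maximum item
scores,

    G = sum_i sum_j |x_i - x_j| / (2 n^2 xbar),

computed here in O(n log n) via the sorted-vector identity.  ``G`` is 0 for
a perfectly equal population (including the all-zero start, by convention)
and is bounded above by 1 - 1/n; the *normalized* variant multiplies by
n/(n-1) so that a single holder of everything scores exactly 1.  A
rank-based variant replaces tier scores with item ranks (tiers) to check
robustness of inequality trends to the score ladder.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .domain import Item

__all__ = [
    "gini",
    "normalized_gini",
    "rank_gini",
    "centralities",
    "innovator_report",
    "inequality_trace",
]

# role labels used in centrality reports
ROLE_CROSSOVER = "crossover-discoverer"
ROLE_A = "A-terminal discoverer"
ROLE_B = "B-terminal discoverer"
ROLE_OTHER = "other"


def _gini_sorted(xs: Sequence[float]) -> float:
    """Gini of a non-negative vector; no validation (hot path)."""
    n = len(xs)
    total = sum(xs)
    if total == 0:
        return 0.0
    s = sorted(xs)
    # sum_i sum_j |x_i - x_j| = 2 * sum_i (2i - n + 1) * x_(i)   (i 0-based)
    acc = 0.0
    for i, x in enumerate(s):
        acc += (2 * i - n + 1) * x
    return acc / (n * total)


def gini(x: Iterable[float]) -> float:
    """Gini coefficient of per-agent scores (mean absolute difference form).

    Defined as 0 when all scores are zero (the pre-discovery population is
    perfectly equal).  Requires n >= 2 and non-negative scores.
    """
    xs = [float(v) for v in x]
    if len(xs) < 2:
        raise ValueError("gini needs at least 2 agents")
    if any(v < 0 for v in xs):
        raise ValueError("gini is defined for non-negative scores only")
    return _gini_sorted(xs)


def normalized_gini(x: Iterable[float]) -> float:
    """Small-sample corrected Gini, ``gini(x) * n / (n - 1)``; in [0, 1]."""
    xs = [float(v) for v in x]
    n = len(xs)
    return gini(xs) * n / (n - 1)


def rank_gini(inventories: Iterable[Iterable[Item]]) -> float:
    """Gini over per-agent maximum item *rank* (tier) instead of tier score."""
    ranks = [max((it.rank for it in inv), default=0) for inv in inventories]
    return gini(ranks)


def centralities(net: nx.Graph, roles: dict[int, str] | None = None) -> pd.DataFrame:
    """Normalized degree, betweenness and closeness centrality per agent.

    Returns a DataFrame indexed by agent id with columns ``degree``,
    ``betweenness``, ``closeness`` and ``role`` (defaulting to "other").
    Computed on the unweighted topology; requires a connected network.
    """
    if not nx.is_connected(net):
        raise ValueError("centralities need a connected network")
    deg = nx.degree_centrality(net)
    btw = nx.betweenness_centrality(net, normalized=True)
    clo = nx.closeness_centrality(net)
    df = pd.DataFrame(
        {
            "degree": pd.Series(deg),
            "betweenness": pd.Series(btw),
            "closeness": pd.Series(clo),
        }
    ).sort_index()
    df["role"] = ROLE_OTHER
    if roles:
        for node, role in roles.items():
            df.loc[node, "role"] = role
    return df


def innovator_report(result, net: nx.Graph | None = None) -> pd.DataFrame:
    """Centralities labelled by discovery role for one finished run.

    Crossover discoverers take precedence over terminal discoverers when an
    agent holds both roles.  If the run achieved no crossover that role is
    simply absent from the report.  ``net`` defaults to the run's final
    network.
    """
    net = net if net is not None else result.network
    roles: dict[int, str] = {}
    fd = result.first_discoverers
    for key, label in (("a_terminal", ROLE_A), ("b_terminal", ROLE_B)):
        if key in fd:
            for node in fd[key][1]:
                roles.setdefault(node, label)
    if "crossover" in fd:
        for node in fd["crossover"][1]:
            roles[node] = ROLE_CROSSOVER
    return centralities(net, roles)


def inequality_trace(result) -> pd.DataFrame:
    """Per-step Gini with the time axis normalized to the crossover.

    Steps 1..T_cross map linearly onto [0, 1] (0 at the first step, 1 at
    the crossover step); any post-crossover steps continue past 1 with the
    same increment.  Requires a run that achieved a crossover (there is
    nothing to normalize otherwise), typically executed with
    ``post_crossover_steps > 0``.
    """
    if not result.crossover_achieved:
        raise ValueError("inequality_trace needs a run that reached a crossover")
    t_cross = result.steps_to_crossover
    g = np.asarray(result.gini_series, dtype=float)
    steps = np.arange(1, len(g) + 1)
    denom = max(t_cross - 1, 1)
    time = (steps - 1) / denom
    return pd.DataFrame({"time": time, "step": steps, "gini": g})
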