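"""The Potions Task dynamics.

One *step* (epoch) proceeds as follows.  Every agent, in a freshly
shuffled order, acts once as a focal combiner: it selects a partner among
its network neighbours (uniformly, or proportionally to edge weight on
weighted networks), a fair coin decides whether the focal contributes one
or two of the three items, both sides draw their contribution from their
own inventories without replacement with probability proportional to item
innovation score, and the pooled triad is checked against the recipe
table.  A valid combination adds the product to both inventories; when
the innovation is new to the dyad, each distinct neighbour of either
member that lacks it receives it with independent probability
``diffusion`` (a rediscovery of an item the dyad already holds spreads
nothing).  After all combinations, each agent
independently rewires one of its links with probability ``rewire``.
Finally the per-step metrics (mean score, Gini, max score) are recorded.
A run ends when any agent holds the tier-4 crossover item (score 358) or
after ``max_steps`` epochs; ``post_crossover_steps`` extra epochs may be
appended for inequality-persistence traces.

Randomness: a single ``random.Random(seed)`` stream drives network
generation (for generated topologies) and every simulation choice, in the
fixed order implied by the loop above, so equal ``(config, seed)`` gives
bit-identical results.
"""

from __future__ import annotations

import json
import random
from bisect import bisect_right
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import networkx as nx

from .domain import (
    CROSSOVER_SCORE,
    Item,
    RecipeTable,
    Trajectory,
    default_recipe_table,
    load_recipe_table,
)
from .metrics import _gini_sorted
from . import networks as _networks

__all__ = [
    "NetworkSpec",
    "SimConfig",
    "RunResult",
    "AgentState",
    "Simulation",
    "run",
    "split_contribution",
    "selection_weights",
    "sample_items",
    "rewire",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class NetworkSpec:
    """Recipe for building the run's network.

    ``kind`` is one of ``er`` (connectedness-conditioned Erdős–Rényi,
    needs ``n`` and ``p``), ``ring`` (needs ``n``), ``complete`` (needs
    ``n``), ``caveman`` (needs ``num_cliques`` and ``clique_size``),
    ``karate`` (the standard 34-node Zachary karate club) or ``edgelist``
    (needs ``path``; set ``weighted`` for weighted files).
    """

    kind: str
    n: int | None = None
    p: float | None = None
    num_cliques: int | None = None
    clique_size: int | None = None
    path: str | None = None
    weighted: bool = False

    def build(self, rng: random.Random) -> nx.Graph:
        if self.kind == "er":
            return _networks.make_random_network(self.n, self.p, seed=rng)
        if self.kind == "ring":
            return _networks.make_ring(self.n)
        if self.kind == "complete":
            return _networks.make_complete(self.n)
        if self.kind == "caveman":
            return _networks.make_connected_caveman(self.num_cliques, self.clique_size)
        if self.kind == "karate":
            g = nx.karate_club_graph()
            g.graph["weighted"] = False
            return g
        if self.kind == "edgelist":
            return _networks.load_edge_list(self.path, weighted=self.weighted)
        raise ValueError(f"unknown network kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


@dataclass
class SimConfig:
    """Parameters of one run.

    ``network`` is a :class:`NetworkSpec` or a prebuilt ``networkx.Graph``
    (nodes are relabelled to 0..N-1 if needed).  ``diffusion`` is the
    per-neighbour probability that a fresh discovery spreads along an
    edge; ``rewire`` the per-agent per-step probability of replacing one
    link.  ``recipe_path`` of ``None`` selects the bundled recipe table.
    """

    network: NetworkSpec | nx.Graph
    diffusion: float = 1.0
    rewire: float = 0.0
    max_steps: int = 1000
    post_crossover_steps: int = 0
    seed: int = 0
    recipe_path: str | None = None

    def validate(self) -> None:
        if not 0.0 <= self.diffusion <= 1.0:
            raise ValueError(f"diffusion must be in [0, 1], got {self.diffusion}")
        if not 0.0 <= self.rewire <= 1.0:
            raise ValueError(f"rewire must be in [0, 1], got {self.rewire}")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.post_crossover_steps < 0:
            raise ValueError("post_crossover_steps must be >= 0")
        if isinstance(self.network, nx.Graph):
            if self.network.number_of_nodes() < 2:
                raise ValueError("network needs at least 2 agents")
        elif not isinstance(self.network, NetworkSpec):
            raise ValueError("network must be a NetworkSpec or a networkx.Graph")

    def to_dict(self) -> dict:
        if isinstance(self.network, nx.Graph):
            net = {"kind": "prebuilt", "n": self.network.number_of_nodes()}
        else:
            net = self.network.to_dict()
        return {
            "network": net,
            "diffusion": self.diffusion,
            "rewire": self.rewire,
            "max_steps": self.max_steps,
            "post_crossover_steps": self.post_crossover_steps,
            "seed": self.seed,
            "recipe_path": self.recipe_path,
        }


# ---------------------------------------------------------------------------
# results

@dataclass
class RunResult:
    """Everything recorded about one run (JSON-serializable via to_dict)."""

    steps: int
    steps_to_crossover: int | None
    crossover_achieved: bool
    n_agents: int
    combinations: int
    mean_score_series: list[float]
    gini_series: list[float]
    max_score_series: list[float]
    final_scores: list[float]
    final_tiers: list[int]
    final_inventories: list[list[str]]
    first_creation: dict[str, tuple[int, tuple[int, int]]]
    first_discoverers: dict[str, tuple[int, tuple[int, int]]]
    seed: int
    config: dict
    network: nx.Graph = field(repr=False, compare=False, default=None)

    @property
    def final_gini(self) -> float:
        return self.gini_series[-1]

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "network"}
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


# ---------------------------------------------------------------------------
# standalone operations (shared by the engine and usable on their own)

def split_contribution(rng: random.Random) -> tuple[int, int]:
    """How many items the focal vs. the partner contributes: (1,2) or (2,1),
    each with probability 1/2; counts always sum to 3."""
    return (1, 2) if rng.random() < 0.5 else (2, 1)


def selection_weights(inventory: Iterable[Item]) -> dict[str, float]:
    """Item-selection probabilities: each item's innovation score divided by
    the inventory's score sum."""
    items = list(inventory)
    if not items:
        raise ValueError("selection_weights needs a non-empty inventory")
    total = sum(it.innovation_score for it in items)
    return {it.name: it.innovation_score / total for it in items}


def _weighted_sample(weights: Sequence[float], k: int, rng: random.Random) -> list[int]:
    """k distinct indices, drawn sequentially without replacement with
    probability proportional to weight (renormalized after each draw)."""
    m = len(weights)
    if k > m:
        raise ValueError(f"cannot draw {k} items from {m}")
    chosen: list[int] = []
    remaining = list(range(m))
    total = float(sum(weights))
    for _ in range(k):
        r = rng.random() * total
        acc = 0.0
        pick = remaining[-1]
        for idx in remaining:
            acc += weights[idx]
            if r < acc:
                pick = idx
                break
        chosen.append(pick)
        remaining.remove(pick)
        total -= weights[pick]
    return chosen


def sample_items(inventory: Iterable[Item], k: int, rng: random.Random) -> list[Item]:
    """Draw ``k`` distinct items, score-proportionally without replacement.

    The inventory is iterated in name order so that equal seeds give equal
    draws regardless of set iteration order.
    """
    items = sorted(inventory, key=lambda it: it.name)
    idxs = _weighted_sample([it.innovation_score for it in items], k, rng)
    return [items[i] for i in idxs]


def rewire(net: nx.Graph, agent, r: float, rng: random.Random):
    """With probability ``r``, replace one random incident edge of ``agent``
    with an edge to a uniformly random current non-neighbour.

    Degree of ``agent`` and the total edge count are conserved; edge
    attributes (weights) move with the link.  No-op when the agent is
    isolated or has no non-neighbour (complete graph).  Returns
    ``(removed_partner, added_partner)`` or ``None`` if nothing changed.
    Draws nothing from ``rng`` when ``r == 0``.
    """
    if r <= 0.0:
        return None
    if rng.random() >= r:
        return None
    nbrs = list(net.neighbors(agent))
    if not nbrs:
        return None
    non = [v for v in net.nodes if v != agent and not net.has_edge(agent, v)]
    if not non:
        return None
    old = nbrs[rng.randrange(len(nbrs))]
    new = non[rng.randrange(len(non))]
    data = dict(net.get_edge_data(agent, old))
    net.remove_edge(agent, old)
    net.add_edge(agent, new, **data)
    return old, new


# ---------------------------------------------------------------------------
# engine internals

class _CompiledTable:
    """Recipe table flattened to integer item ids for the hot loop."""

    __slots__ = (
        "table", "names", "id_of", "weight", "tier_score", "tier",
        "recipes", "crossover_id", "basic_ids", "a_terminal_id", "b_terminal_id",
    )

    def __init__(self, table: RecipeTable):
        self.table = table
        self.names = sorted(table.items)
        self.id_of = {n: i for i, n in enumerate(self.names)}
        self.weight = [table.items[n].innovation_score for n in self.names]
        self.tier_score = [table.items[n].tier_score for n in self.names]
        self.tier = [table.items[n].tier for n in self.names]
        self.recipes = {
            frozenset(self.id_of[n] for n in triad): self.id_of[prod]
            for triad, prod in table.recipes.items()
        }
        self.crossover_id = self.id_of[table.crossover_item.name]
        self.basic_ids = [self.id_of[it.name] for it in table.basics()]
        terminals = {
            it.trajectory: self.id_of[it.name]
            for it in table.items.values()
            if it.tier == 3
        }
        self.a_terminal_id = terminals[Trajectory.A]
        self.b_terminal_id = terminals[Trajectory.B]


class AgentState:
    """An agent's inventory (grow-only) and derived score.

    The inventory is kept three ways for the hot loop: a membership set of
    item ids, the insertion-ordered id list, and the matching cumulative
    innovation-weight list used for proportional sampling.
    """

    __slots__ = ("id", "items", "order", "w", "cum", "total", "score", "max_tier")

    def __init__(self, agent_id: int, ct: _CompiledTable):
        self.id = agent_id
        self.items: set[int] = set()
        self.order: list[int] = []
        self.w: list[float] = []
        self.cum: list[float] = []
        self.total = 0.0
        self.score = 0.0
        self.max_tier = 0
        for item_id in ct.basic_ids:
            self.add(item_id, ct)

    def add(self, item_id: int, ct: _CompiledTable) -> bool:
        """Add an item if absent; returns True when the inventory grew."""
        if item_id in self.items:
            return False
        self.items.add(item_id)
        self.order.append(item_id)
        w = ct.weight[item_id]
        self.w.append(w)
        self.total += w
        self.cum.append(self.total)
        ts = ct.tier_score[item_id]
        if ts > self.score:
            self.score = ts
        t = ct.tier[item_id]
        if t > self.max_tier:
            self.max_tier = t
        return True

    def inventory_names(self, ct: _CompiledTable) -> list[str]:
        return [ct.names[i] for i in self.order]

    def inventory(self, ct: _CompiledTable) -> set[Item]:
        return {ct.table.items[ct.names[i]] for i in self.order}


class Simulation:
    """A single mutable run of the model; use :func:`run` for one-shot use."""

    def __init__(
        self,
        config: SimConfig,
        table: RecipeTable | None = None,
        graph: nx.Graph | None = None,
    ):
        config.validate()
        self.config = config
        self.rng = random.Random(config.seed)
        if table is None:
            table = (
                load_recipe_table(config.recipe_path)
                if config.recipe_path
                else default_recipe_table()
            )
        self.ct = _CompiledTable(table)

        if graph is None:
            if isinstance(config.network, nx.Graph):
                graph = config.network.copy()
            else:
                graph = config.network.build(self.rng)
        else:
            graph = graph.copy()
        if sorted(graph.nodes) != list(range(graph.number_of_nodes())):
            graph = nx.convert_node_labels_to_integers(graph, ordering="sorted")
        self.net = graph
        self.n = graph.number_of_nodes()
        self.weighted = bool(graph.graph.get("weighted", False)) or any(
            "weight" in d for _, _, d in graph.edges(data=True)
        )

        self.agents = [AgentState(i, self.ct) for i in range(self.n)]
        self._adj: list[list[int]] = [list(graph.neighbors(i)) for i in range(self.n)]
        self._wcum: list[list[float] | None] = [None] * self.n

        self.steps = 0
        self.steps_to_crossover: int | None = None
        self.first_creation: dict[str, tuple[int, tuple[int, int]]] = {}
        self.mean_score_series: list[float] = []
        self.gini_series: list[float] = []
        self.max_score_series: list[float] = []
        self._order = list(range(self.n))

    # -- per-agent choices -------------------------------------------------

    def select_partner(self, focal: int) -> int | None:
        """A neighbour of ``focal``: uniform, or edge-weight proportional on
        weighted networks.  ``None`` when the focal is isolated (skip)."""
        nbrs = self._adj[focal]
        if not nbrs:
            return None
        if not self.weighted:
            return nbrs[self.rng.randrange(len(nbrs))]
        cum = self._wcum[focal]
        if cum is None:
            acc, cum = 0.0, []
            edges = self.net[focal]
            for v in nbrs:
                acc += edges[v].get("weight", 1.0)
                cum.append(acc)
            self._wcum[focal] = cum
        r = self.rng.random() * cum[-1]
        return nbrs[bisect_right(cum, r)]

    def _draw_ids(self, ag: AgentState, k: int) -> tuple[int, ...]:
        # score-proportional draw of k (1 or 2) distinct item ids
        rng_random = self.rng.random
        cum = ag.cum
        total = ag.total
        i1 = bisect_right(cum, rng_random() * total)
        first = ag.order[i1]
        if k == 1:
            return (first,)
        w = ag.w
        r2 = rng_random() * (total - w[i1])
        acc = 0.0
        order = ag.order
        for j in range(len(order)):
            if j == i1:
                continue
            acc += w[j]
            if r2 < acc:
                return (first, order[j])
        # float round-off: fall back to the last other item
        j = len(order) - 1 if i1 != len(order) - 1 else len(order) - 2
        return (first, order[j])

    def attempt_combination(self, focal: int, partner: int) -> Item | None:
        """One dyadic combination attempt; adds the product to both
        inventories and returns it when the pooled triad is a recipe."""
        item, _ = self._attempt(focal, partner)
        return item

    def _attempt(self, focal: int, partner: int) -> tuple[Item | None, bool]:
        # returns (product, whether it was new to at least one dyad member)
        ag_f = self.agents[focal]
        ag_p = self.agents[partner]
        kf, kp = split_contribution(self.rng)
        drawn = self._draw_ids(ag_f, kf) + self._draw_ids(ag_p, kp)
        key = frozenset(drawn)
        if len(key) != 3:
            return None, False
        prod = self.ct.recipes.get(key)
        if prod is None:
            return None, False
        name = self.ct.names[prod]
        if name not in self.first_creation:
            self.first_creation[name] = (self.steps + 1, (focal, partner))
        new_f = ag_f.add(prod, self.ct)
        new_p = ag_p.add(prod, self.ct)
        return self.ct.table.items[name], new_f or new_p

    def diffuse(self, item: Item, focal: int, partner: int) -> set[int]:
        """Spread ``item`` one hop from the discovering dyad.

        Every distinct neighbour of either dyad member that lacks the item
        receives it with one independent Bernoulli(``diffusion``) draw (a
        neighbour of both members still gets a single chance, so on a
        complete network a fraction ``d`` of the population acquires the
        innovation in expectation).  Recipients do not re-diffuse.
        Returns the recipient ids."""
        d = self.config.diffusion
        recipients: set[int] = set()
        if d <= 0.0:
            return recipients
        item_id = self.ct.id_of[item.name]
        rng_random = self.rng.random
        agents = self.agents
        seen: set[int] = set()
        for member in (focal, partner):
            for nb in self._adj[member]:
                if nb in seen:
                    continue
                seen.add(nb)
                ag = agents[nb]
                if item_id not in ag.items and (d >= 1.0 or rng_random() < d):
                    ag.add(item_id, self.ct)
                    recipients.add(nb)
        return recipients

    def rewire_agent(self, agent: int) -> tuple[int, int] | None:
        """Apply the per-agent rewiring rule and keep the caches in sync."""
        change = rewire(self.net, agent, self.config.rewire, self.rng)
        if change is not None:
            old, new = change
            self._adj[agent] = list(self.net.neighbors(agent))
            self._adj[old] = list(self.net.neighbors(old))
            self._adj[new] = list(self.net.neighbors(new))
            if self.weighted:
                for node in (agent, old, new):
                    self._wcum[node] = None
        return change

    # -- the epoch ---------------------------------------------------------

    def step(self) -> None:
        """One epoch: every agent acts once as focal (shuffled order), then
        the rewiring pass, then metric recording."""
        rng = self.rng
        order = self._order
        rng.shuffle(order)
        for focal in order:
            partner = self.select_partner(focal)
            if partner is None:
                continue
            item, fresh = self._attempt(focal, partner)
            # diffusion only fires when the innovation is new to the dyad;
            # a rediscovery of an item both members already hold spreads nothing
            if fresh:
                self.diffuse(item, focal, partner)
        if self.config.rewire > 0.0:
            rng.shuffle(order)
            for agent in order:
                self.rewire_agent(agent)
        self.steps += 1
        scores = [ag.score for ag in self.agents]
        self.mean_score_series.append(sum(scores) / self.n)
        self.max_score_series.append(max(scores))
        self.gini_series.append(_gini_sorted(scores))
        if (
            self.steps_to_crossover is None
            and self.ct.names[self.ct.crossover_id] in self.first_creation
        ):
            self.steps_to_crossover = self.steps

    @property
    def crossover_achieved(self) -> bool:
        return self.steps_to_crossover is not None

    def run(self) -> RunResult:
        """Iterate epochs to crossover or the step cap, then any configured
        post-crossover epochs; package the result."""
        cfg = self.config
        while self.steps < cfg.max_steps and not self.crossover_achieved:
            self.step()
        if self.crossover_achieved:
            for _ in range(cfg.post_crossover_steps):
                self.step()
        ct = self.ct
        roles = {
            ct.names[ct.a_terminal_id]: "a_terminal",
            ct.names[ct.b_terminal_id]: "b_terminal",
            ct.names[ct.crossover_id]: "crossover",
        }
        first_discoverers = {
            roles[name]: rec
            for name, rec in self.first_creation.items()
            if name in roles
        }
        return RunResult(
            steps=self.steps,
            steps_to_crossover=self.steps_to_crossover,
            crossover_achieved=self.crossover_achieved,
            n_agents=self.n,
            combinations=self.steps * self.n,
            mean_score_series=list(self.mean_score_series),
            gini_series=list(self.gini_series),
            max_score_series=list(self.max_score_series),
            final_scores=[ag.score for ag in self.agents],
            final_tiers=[ag.max_tier for ag in self.agents],
            final_inventories=[ag.inventory_names(ct) for ag in self.agents],
            first_creation=dict(self.first_creation),
            first_discoverers=first_discoverers,
            seed=cfg.seed,
            config=cfg.to_dict(),
            network=self.net,
        )


def run(
    config: SimConfig,
    table: RecipeTable | None = None,
    graph: nx.Graph | None = None,
) -> RunResult:
    """Execute one run of the Potions Task and return its :class:`RunResult`."""
    return Simulation(config, table=table, graph=graph).run()
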