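"""Batch experiments: replicate sweeps, presets and summaries.

A :class:`SweepSpec` is a list of parameter *cells* (each resolving to a
:class:`~potionsim.engine.SimConfig`) run for a number of replicates.
Replicate seeds are derived counter-style from ``(base_seed, cell index,
replicate index)`` through ``numpy.random.SeedSequence``, so any subset of
the grid can be (re)run in any order — serial or parallel — and produce
the identical table.

Presets mirror the studied designs: connectivity/diffusion/rewiring
sweeps on random networks, the per-capita long-horizon sweep, the
inequality-persistence design, the centrality design, the real-world
network batch and the caveman clique-composition sweep.  The replicate
count defaults to a desk scale of 100 per cell; ``scale=10`` gives the
full 1000-replicate scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .domain import RecipeTable, default_recipe_table
from .engine import NetworkSpec, RunResult, SimConfig, Simulation
from . import metrics as _metrics
from . import networks as _networks

__all__ = [
    "SweepSpec",
    "replicate_seed",
    "sweep",
    "run_replicates",
    "preset",
    "PRESETS",
    "summarize",
    "make_fixture",
]

log = logging.getLogger("potionsim")

#: directory where real-world edge lists are expected (not bundled; the
#: published deposits hold them)
REAL_WORLD_DIR = "data/real_world"


@dataclass
class SweepSpec:
    """A grid of simulation cells with a replicate count and base seed."""

    name: str
    cells: list[SimConfig]
    replicates: int = 100
    base_seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for c in self.cells:
            c.validate()


def replicate_seed(base_seed: int, cell: int, rep: int) -> int:
    """Deterministic per-replicate seed, independent of execution order."""
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(cell, rep))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _cell_columns(cfg: SimConfig) -> dict:
    net = cfg.to_dict()["network"]
    return {
        "network_kind": net.get("kind"),
        "n": net.get("n"),
        "p": net.get("p"),
        "num_cliques": net.get("num_cliques"),
        "clique_size": net.get("clique_size"),
        "edgelist": net.get("path"),
        "weighted": net.get("weighted", False),
        "diffusion": cfg.diffusion,
        "rewire": cfg.rewire,
        "max_steps": cfg.max_steps,
        "post_crossover_steps": cfg.post_crossover_steps,
    }


RESULT_COLUMNS = [
    "sweep", "cell", "replicate", "network_kind", "n", "p", "num_cliques",
    "clique_size", "edgelist", "weighted", "diffusion", "rewire", "max_steps",
    "post_crossover_steps", "seed", "steps", "steps_to_crossover",
    "crossover_achieved", "combinations", "combinations_to_crossover",
    "mean_score", "max_score", "gini", "gini_normalized", "gini_rank",
]


def run_replicates(
    cfg: SimConfig,
    replicates: int,
    base_seed: int = 0,
    cell_index: int = 0,
    table: RecipeTable | None = None,
    keep_results: bool = False,
    graph: nx.Graph | None = None,
):
    """Run one cell for ``replicates`` independent seeds.

    Returns ``(rows, results)`` where ``rows`` is a list of flat summary
    dicts (one per replicate) and ``results`` the full
    :class:`RunResult` objects if ``keep_results`` (else ``None``).  A
    prebuilt ``graph`` (e.g. a loaded real-world network) short-circuits
    network construction for every replicate.
    """
    table = table or default_recipe_table()
    if graph is None and isinstance(cfg.network, nx.Graph):
        graph = cfg.network
    rows = []
    results = [] if keep_results else None
    base_cols = _cell_columns(cfg)
    for rep in range(replicates):
        seed = replicate_seed(base_seed, cell_index, rep)
        rcfg = replace(cfg, seed=seed)
        res = Simulation(rcfg, table=table, graph=graph).run()
        n = res.n_agents
        rows.append(
            {
                "cell": cell_index,
                "replicate": rep,
                **base_cols,
                "seed": seed,
                "steps": res.steps,
                "steps_to_crossover": res.steps_to_crossover,
                "crossover_achieved": res.crossover_achieved,
                "combinations": res.combinations,
                "combinations_to_crossover": (
                    res.steps_to_crossover * n if res.crossover_achieved else None
                ),
                "mean_score": res.mean_score_series[-1],
                "max_score": res.max_score_series[-1],
                "gini": res.final_gini,
                "gini_normalized": res.final_gini * n / (n - 1),
                "gini_rank": _metrics.gini(res.final_tiers),
            }
        )
        if keep_results:
            results.append(res)
    return rows, results


def sweep(spec: SweepSpec, table: RecipeTable | None = None) -> pd.DataFrame:
    """Run every (cell, replicate) pair of ``spec``; one row per replicate.

    Deterministic given ``spec.base_seed``; cells are validated up front
    so an invalid cell fails before any simulation work.
    """
    table = table or default_recipe_table()
    for cfg in spec.cells:
        cfg.validate()
    all_rows: list[dict] = []
    for i, cfg in enumerate(spec.cells):
        log.info("sweep %s: cell %d/%d", spec.name, i + 1, len(spec.cells))
        rows, _ = run_replicates(
            cfg, spec.replicates, base_seed=spec.base_seed, cell_index=i, table=table
        )
        all_rows.extend(rows)
    df = pd.DataFrame(all_rows, columns=[c for c in RESULT_COLUMNS if c != "sweep"])
    df.insert(0, "sweep", spec.name)
    return df


# ---------------------------------------------------------------------------
# presets

_SIZES = (10, 25, 50, 100)
_EDGE_PS = (0.05, 0.1, 0.25, 0.5, 1.0)

_REAL_WORLD = (
    ("baboon", True),
    ("chimp", True),
    ("karate_club", False),
    ("coastal_agta", True),
    ("forest_agta", True),
    ("department", False),
)


def _er(n, p, **kw) -> SimConfig:
    return SimConfig(network=NetworkSpec("er", n=n, p=p), **kw)


def preset(name: str, scale: float = 1.0) -> SweepSpec:
    """A named experiment design, with replicates = round(100 * scale).

    ``scale=1`` is the desk scale (100 replicates per cell); ``scale=10``
    matches the published 1000-replicate scale.
    """
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    cells = PRESETS[name]()
    reps = max(1, round(100 * scale))
    return SweepSpec(name=name, cells=cells, replicates=reps)


def _feasible(n: int, p: float) -> bool:
    # connectedness-conditioned ER needs a workable expected degree
    return p * (n - 1) >= 2.0


def _fig2_connectivity():
    return [_er(n, p) for n in _SIZES for p in _EDGE_PS if _feasible(n, p)]


def _fig2_diffusion():
    return [
        SimConfig(network=NetworkSpec("complete", n=n), diffusion=d)
        for n in _SIZES
        for d in (0.1, 0.25, 0.5, 0.75, 1.0)
    ]


def _fig2_rewire():
    return [_er(100, 0.05, rewire=r) for r in (0.0, 0.1, 0.25, 0.5, 1.0)]


def _fig3_percapita():
    # p fixed across sizes; 0.25 keeps the n=10 cell connectable
    return [_er(n, 0.25, max_steps=10_000) for n in _SIZES]


def _fig4_persistence():
    return [
        _er(50, p, post_crossover_steps=100) for p in _EDGE_PS if _feasible(50, p)
    ]


def _fig5_centrality():
    return [_er(100, 0.05)]


def _table1_realworld():
    cells = []
    for net_name, weighted in _REAL_WORLD:
        if net_name == "karate_club":
            spec = NetworkSpec("karate")
        else:
            spec = NetworkSpec(
                "edgelist",
                path=f"{REAL_WORLD_DIR}/{net_name}.csv",
                weighted=weighted,
            )
        cells.append(SimConfig(network=spec))
    return cells


def _caveman_cliques():
    # 24 agents, composition varied from few large to many small cliques
    return [
        SimConfig(network=NetworkSpec("caveman", num_cliques=l, clique_size=k))
        for l, k in ((2, 12), (3, 8), (4, 6), (6, 4), (8, 3))
    ]


PRESETS = {
    "fig2_connectivity": _fig2_connectivity,
    "fig2_diffusion": _fig2_diffusion,
    "fig2_rewire": _fig2_rewire,
    "fig3_percapita": _fig3_percapita,
    "fig4_persistence": _fig4_persistence,
    "fig5_centrality": _fig5_centrality,
    "table1_realworld": _table1_realworld,
    "caveman_cliques": _caveman_cliques,
}


# ---------------------------------------------------------------------------
# summaries

_SUMMARY_VALUES = (
    "steps_to_crossover",
    "combinations_to_crossover",
    "gini",
    "gini_normalized",
    "gini_rank",
)


def summarize(table: pd.DataFrame, group_by: list[str] | str) -> pd.DataFrame:
    """Per-group mean, standard error and replicate count of the headline
    quantities, plus the crossover success rate.

    Runs that hit the step cap without a crossover are excluded from the
    step/combination means (they are censored, not observed); the
    ``crossover_rate`` column reports their share.  Groups with a single
    replicate get SE 0 and ``se_undefined=True``.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    if table.empty:
        raise ValueError("summarize needs a non-empty results table")
    unknown = [g for g in group_by if g not in table.columns]
    if unknown:
        raise ValueError(f"unknown group field(s): {unknown}")

    def _agg(g: pd.DataFrame) -> pd.Series:
        out: dict = {"replicates": len(g)}
        out["crossover_rate"] = float(g["crossover_achieved"].mean())
        ok = g[g["crossover_achieved"]]
        for col in _SUMMARY_VALUES:
            vals = (ok if col in ("steps_to_crossover", "combinations_to_crossover") else g)[
                col
            ].dropna()
            out[f"{col}_mean"] = float(vals.mean()) if len(vals) else float("nan")
            out[f"{col}_se"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
            )
        out["se_undefined"] = len(g) < 2
        return pd.Series(out)

    grouped = table.groupby(group_by, dropna=False).apply(_agg, include_groups=False)
    return grouped.reset_index()


# ---------------------------------------------------------------------------
# fixtures

def make_fixture(kind: str):
    """Small deterministic objects for tests and examples.

    ``toy_recipes``: the bundled (structurally valid fallback) recipe
    table; ``toy_network``: a fixed connected 6-node graph;
    ``tiny_run``: a completed 2-agent run with a fixed seed.
    """
    if kind == "toy_recipes":
        return default_recipe_table()
    if kind == "toy_network":
        g = nx.Graph([(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0), (1, 4)])
        g.graph["weighted"] = False
        return g
    if kind == "tiny_run":
        cfg = SimConfig(network=NetworkSpec("complete", n=2), max_steps=2000, seed=7)
        return Simulation(cfg).run()
    raise ValueError(
        "unknown fixture kind; available: toy_recipes, toy_network, tiny_run"
    )
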