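# Methods

## Model

The Potions Task is a cumulative, recombinatorial exploration game.
Items live on two path-dependent trajectories (A and B) plus one
crossover item:

| tier | items | tier score | recipe shape |
|------|-------|-----------:|--------------|
| 0 | a1 a2 a3 / b1 b2 b3 | 0 | given at start (innovation scores 6/8/10 per trajectory) |
| 1 | 1a / 1b | 48 | the three basics of the trajectory |
| 2 | 2a / 2b | 109 | tier-1 item + two same-trajectory basics |
| 3 | 3a / 3b | 188 | tier-2 item + two same-trajectory basics |
| 4 | x | 358 | both tier-3 terminals + a basic |

An item's *innovation score* doubles as its selection weight; for
discovered items it equals the tier score, so fresh discoveries dominate
subsequent draws and exploration rarely returns to the basics — the
model's path dependency. An agent's *score* is the maximum tier score in
its inventory; inventories only grow.

**Recipe table provenance.** The exact tier-2/3 triads of the original
game are published only as a figure; the bundled table
(`data/recipes_fallback.csv`) is a *structural fallback*, synthetic but
satisfying every structural constraint above (and validated by
`validate_recipe_table`). Any table with the same structure can be
substituted via `SimConfig.recipe_path`. Absolute quantities (e.g. mean
steps to crossover) depend mildly on the exact triads; the structural
properties driving the results — two trajectories, an increasing weight
ladder, a crossover needing both terminals — are preserved.

## Dynamics

One epoch (`Simulation.step`):

1. agents act once each as focal combiner, in a freshly shuffled order;
   an agent may additionally serve as partner any number of times;
2. the focal picks a partner uniformly among neighbours (proportionally
   to edge weight on weighted networks); isolated agents skip their turn;
3. a fair coin sets the focal/partner contribution split, (1,2) or (2,1);
   each side draws its items from its own inventory, sequentially
   without replacement, with probability proportional to innovation
   score; a pooled triad with fewer than three distinct names is invalid;
4. a valid triad adds the product to both inventories; if the product is
   **new to at least one dyad member**, each distinct neighbour of
   either member that lacks it receives it with one independent
   Bernoulli(d) draw (a rediscovery both members already hold spreads
   nothing, and a common neighbour of both members gets a single chance
   — so on a complete network a fraction d of the population acquires a
   fresh innovation in expectation);
5. after all combinations, each agent rewires with probability r: one
   uniformly random incident edge is removed and replaced by an edge to
   a uniformly random non-neighbour (degree of the rewiring agent and
   total edge count conserved; edge attributes travel with the link;
   no-op for isolated agents or complete graphs). Rewiring may
   disconnect the graph; no repair is attempted;
6. per-epoch metrics are recorded (mean score, Gini, max score).

A run ends at the first epoch in which any agent holds the tier-4 item,
or after `max_steps` epochs (default 1000; 10 000 for the long-horizon
per-capita design); `post_crossover_steps` extra epochs (100 in the
persistence design) can be appended. First-discoverer credit for an item
goes to both members of the dyad whose combination first created it;
diffusion recipients are never credited.

All randomness comes from a single `random.Random(seed)` stream used in
the fixed order above (network generation first, for generated
topologies), so equal configurations are bit-reproducible. Replicate
seeds in sweeps derive from `(base_seed, cell, replicate)` through
`numpy.random.SeedSequence`, making any execution order — or partial
re-execution — produce identical tables.

## Networks

* `make_random_network(n, p)`: Erdős–Rényi conditioned on connectedness
  by rejection (cap 10 000 draws) — every agent needs a partner, and the
  conditioned distribution is what the Monte-Carlo tests check against.
  Preset grids exclude cells with p·(n−1) < 2, where connected draws are
  practically unobtainable.
* `make_ring(n)`, `make_complete(n)`.
* `make_connected_caveman(l, k)`: k ≥ 3 is the standard construction
  (one within-clique edge per clique rewired to the neighbouring clique;
  edge count l·k(k−1)/2 conserved). For k = 2 removing the only
  within-clique edge would isolate a node, so the edge is kept and only
  the inter-clique link is added (a connected cycle-of-dyads with 2l
  edges); edge-count conservation therefore applies for k ≥ 3 only.
* `load_edge_list(path, weighted)`: undirected `source,target[,weight]`
  CSV/TSV; duplicates collapsed (weights summed) and self-loops dropped,
  both with warnings; labels mapped lexicographically to 0..N−1.
* `network_stats`: average path length and clustering are always
  computed on the unweighted topology (the path length reported for the
  karate club in the source literature matches the unweighted
  computation to within rounding). Because the field's use of
  "connectivity" is ambiguous, both the plain and the weighted average
  degree are reported.

## Measures

* `gini`: Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄), computed by the O(n log n) sorted
  identity and cross-checked against the O(n²) definition in tests;
  defined as 0 for the all-zero vector (the pre-discovery population is
  perfectly equal); bounded by 1−1/n.
* `normalized_gini`: × n/(n−1), so a single holder of everything scores
  exactly 1. The normalization used for the published "normalized"
  curves is not stated; both variants are emitted everywhere so either
  convention can be compared.
* `rank_gini`: the same statistic over per-agent maximum item *rank*
  (= tier), a robustness check against the specific score ladder.
* `centralities` / `innovator_report`: normalized degree, betweenness
  and closeness (networkx), joined with discovery roles; crossover
  discoverers take precedence when an agent holds several roles.
* `inequality_trace`: per-epoch Gini on a time axis mapped linearly so 0
  is the first epoch and 1 the crossover epoch; post-crossover epochs
  continue past 1 with the same increment.

## Study conditions and problem sizes

Experiment presets encode the studied designs with diffusion 1 and
rewiring 0 unless they are the manipulated factor: ER grids over
n ∈ {10, 25, 50, 100} × p ∈ {0.05…1} (feasible cells only), diffusion
d ∈ {0.1…1} on complete networks, rewiring r ∈ {0…1} on ER(100, 0.05),
the per-capita design at p = 0.25 with a 10 000-step cap (p fixed across
sizes; 0.25 is the smallest grid value at which 10-agent networks are
reliably connectable), persistence on 50-agent networks with 100
post-crossover epochs, innovator centrality on ER(100, 0.05), the six
real-world networks, and caveman compositions of 24 agents. Replicates
default to a desk scale of 100 per cell (`scale=10` gives the published
1000).

The acceptance suite runs the karate club at the full 1000 replicates
(~20 s) and each trend comparison at 200 replicates, sized so the whole
suite stays within a desktop test budget while leaving the asserted
effects at |z| well past 3.

## What the synthetic conditions do and do not show

Generated networks are connectedness-conditioned ER draws, rings,
caveman graphs and complete graphs; real-world structure (degree
heterogeneity, community structure, weights) enters only through loaded
edge lists. The recipe table is a structural stand-in (above). Agents
are identical — no skill, memory limits, or information loss — so
passing tests demonstrate properties of the *structural* model, not
claims about any particular empirical population.

## Numerical and design choices

* Items are interned to integer ids; inventories keep a membership set,
  the insertion-ordered id list and a cumulative-weight list, making a
  combination attempt O(|inventory|) with small constants (~2–3 µs).
* Weighted draws use cumulative sums with a guard for floating-point
  round-off on the final interval.
* Diffusion consumes no RNG draws at d = 0 or d = 1 (both limits are
  deterministic); the rewiring pass consumes none at r = 0. Each
  documented limit keeps the stream identical across the remaining
  choices.
* Metrics are recorded after the rewiring pass, so a recorded epoch
  reflects the state the next epoch starts from.
* The run's `network` attribute is the final (possibly rewired) graph;
  centrality reports for dynamic networks therefore describe final
  positions.
* `summarize` excludes runs that hit the step cap from step/combination
  means (they are censored observations) and reports their share as
  `crossover_rate`.

## Known limitations

* The bundled recipe triads are structural, not the original game's
  exact triads (see above).
* Only the karate club among the six real-world networks is available
  offline; the others load from user-supplied edge lists.
* Two published observations do not reproduce under this implementation
  and its conditions: the decrease of crossover-time Gini with
  population size (we measure flat-to-increasing across rings and ER
  networks, under both raw and normalized Gini), and the printed karate
  club average path length of 2.42 (the canonical 34-node/78-edge graph
  gives 2.408). The corresponding checks are kept at their stated
  strictness and fail visibly rather than being loosened.
* Rank ("inventory level") is carried as metadata and used only by the
  rank-Gini variant.
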