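"""Edge-based motifs: recovering designed co-fluctuation of information flow.

Simulates a 6-region network in which the per-epoch strengths of edges
A->C and B->D share a latent factor (loading 0.8) while a third coupled
edge E->F fluctuates independently. Correlating the per-epoch dPTE series
of every edge against every other exposes the designed motif: the
comodulated pair correlates far above any node-disjoint pairing of a group
edge with an unrelated edge. (Edge pairs sharing a region are excluded
from the comparison: their metric columns are structurally dependent even
for independent channels.)
"""
import numpy as np

from edgeflow import (
    BAND_TABLE,
    ComodulationGroup,
    DirectedCoupling,
    SimulationConfig,
    build_edge_series,
    dpte_dpte_correlation,
    generate_comotif_recording,
    metrics_for_state,
)

cfg = SimulationConfig(
    n_regions=6,
    region_names=["A", "B", "C", "D", "E", "F"],
    state_schedule=[("RS", 2400.0)],  # 240 ten-second epochs
    coupling_edges=[
        DirectedCoupling(0, 2, {"RS": 10.0}),
        DirectedCoupling(1, 3, {"RS": 10.0}),
        DirectedCoupling(4, 5, {"RS": 10.0}),
    ],
    epoch_coupling_sd=1.0,
    comodulation_groups=[ComodulationGroup(edges=((0, 2), (1, 3)), loading=0.8)],
    seed=0,
)
rec, truth = generate_comotif_recording(cfg)
series = build_edge_series(metrics_for_state(rec, BAND_TABLE["theta"], "RS"))
corr = dpte_dpte_correlation(series, "RS")
de = series.directed_edges

i, j = de.index(("A", "C")), de.index(("B", "D"))
r_in = corr.r[i, j]
k = de.index(("E", "F"))
print(f"designed group   r[dPTE(A->C), dPTE(B->D)] = {r_in:+.3f}  (loading 0.8)")
print(f"unrelated edge   r[dPTE(A->C), dPTE(E->F)] = {corr.r[i, k]:+.3f}")
print(f"ground truth     corr of realized coupling strengths = "
      f"{np.corrcoef(truth.kappa_series(0, 2), truth.kappa_series(1, 3))[0, 1]:+.3f}")

group = {frozenset(("A", "C")), frozenset(("B", "D"))}
best_out = max(
    abs(corr.r[a, b])
    for a, ea in enumerate(de) if frozenset(ea) in group
    for b, eb in enumerate(de)
    if frozenset(eb) not in group and not (frozenset(eb) & frozenset(ea))
)
print(f"max |r| of a group edge with any node-disjoint outside edge = {best_out:.3f}")
print("The designed motif outranks every structurally independent alternative.")
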