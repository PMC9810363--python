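"""Recovering a known direction of information flow with dPTE.

Simulates two theta-band oscillators where region A pulls region B's phase
(A -> B, coupling 25 rad/s), computes per-epoch directed phase transfer
entropy, and shows that the sign of dPTE(A->B) identifies the true
direction in essentially every 10-s epoch, and that the mean dPTE grows
with coupling strength.
"""
import numpy as np

from edgeflow import (
    BAND_TABLE,
    DirectedCoupling,
    SimulationConfig,
    generate_recording,
    metrics_for_state,
)

for kappa in (0.0, 10.0, 25.0):
    cfg = SimulationConfig(
        n_regions=2,
        region_names=["A", "B"],
        state_schedule=[("RS", 600.0)],  # 60 ten-second epochs
        coupling_edges=[DirectedCoupling(0, 1, {"RS": kappa})],
        seed=1,
    )
    rec, _ = generate_recording(cfg)
    metrics = metrics_for_state(rec, BAND_TABLE["theta"], "RS")
    d = np.array([m.dpte_matrix[0, 1] for m in metrics])
    print(f"kappa = {kappa:5.1f} rad/s : mean dPTE(A->B) = {d.mean():+.4f}, "
          f"epochs with correct sign = {100 * np.mean(d > 0):.0f}%")

print("dPTE > 0 means net information outflow A -> B; at zero coupling the")
print("sign is a coin flip, and the mean grows monotonically with coupling.")
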