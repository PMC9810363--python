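"""Segment-shuffle surrogate control for directed flow.

Shuffling the temporal order of each channel's 10-s segments independently
destroys cross-channel alignment while preserving each segment's spectrum.
Under this null the network-mean dPTE collapses to zero, while the observed
coupled edge sits far beyond the null's 95th percentile — the observed flow
is not a filtering or estimation artifact.
"""
import numpy as np

from edgeflow import (
    BAND_TABLE,
    DirectedCoupling,
    SimulationConfig,
    generate_recording,
    metrics_for_state,
    shuffle_surrogate_null,
)

cfg = SimulationConfig(
    n_regions=2,
    region_names=["A", "B"],
    state_schedule=[("RS", 600.0)],  # 60 ten-second segments
    coupling_edges=[DirectedCoupling(0, 1, {"RS": 25.0})],
    seed=5,
)
rec, _ = generate_recording(cfg)
theta = BAND_TABLE["theta"]

null = shuffle_surrogate_null(rec, theta, metric="dpte", n_shuffles=200, seed=5)
metrics = metrics_for_state(rec, theta, "RS")
observed = np.mean([m.dpte_matrix[0, 1] for m in metrics])

print(f"observed mean dPTE(A->B)      : {observed:+.4f}")
print(f"surrogate null mean           : {null.values.mean():+.5f}")
print(f"surrogate null 95th percentile: {null.percentile(95):+.5f}")
print("The null centres at zero; the observed directed flow exceeds its")
print("95th percentile by more than an order of magnitude.")
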