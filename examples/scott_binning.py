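"""Scott-rule phase binning on band-passed noise.

Builds 100 ten-second white-noise epochs at 1000 Hz, band-passes each to
theta (4-8 Hz), extracts the Hilbert phase, and applies the Scott rule
binsize = 3.49 * sd(phase) * N**(-1/3). For near-uniform phases the bin
size sits near 0.294 rad, giving ceil(2*pi/0.294) = 22 phase bins — the
histogram resolution used by every phase-entropy estimate downstream.
"""
import numpy as np

from edgeflow import BAND_TABLE, Epoch, bandpass, hilbert_phase, scott_bin_size

rng = np.random.default_rng(0)
sizes, counts = [], []
for k in range(100):
    epoch = Epoch(rng.standard_normal(10_000), 1000.0, "A", "RS", k)
    scheme = scott_bin_size(hilbert_phase(bandpass(epoch, BAND_TABLE["theta"])))
    sizes.append(scheme.bin_size)
    counts.append(scheme.n_bins)

print(f"median bin size : {np.median(sizes):.4f} rad  (range "
      f"{min(sizes):.4f}-{max(sizes):.4f})")
print(f"modal bin count : {int(np.bincount(counts).argmax())} bins "
      f"({100 * np.mean(np.array(counts) == 22):.0f}% of epochs give exactly 22)")
print("A 10-s, 1000-Hz epoch with near-uniform phases always lands on ~22 bins:")
print("the entropy estimates below therefore share one histogram resolution.")
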