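# edgeflow

Frequency-specific, phase-based directed network analysis for multichannel
field-potential recordings — phase locking value (PLV), binned phase
transfer entropy (PTE), zero-centred directed PTE (dPTE), and an
**edge-based motif framework** that correlates the per-epoch fluctuations of
information flow and functional connectivity across every edge of the
network. A built-in simulator of coupled stochastic phase oscillators with
known directed coupling and designed edge co-fluctuation makes every stage
testable without any recorded data.

It is written for electrophysiologists and network neuroscientists who
record continuous local field potentials (LFP/EEG-like signals) from a
handful of regions across behavioural states and want to ask not only
*"which way does information flow on each pathway?"* but *"which pathways
fluctuate together, and how does flow relate to the network's functional
organization?"*

## The method

A recording (channels × samples, fixed sampling rate, behavioural-state
annotations) is cut into fixed 10-s epochs, band-pass filtered into a
physiological band (theta, 4–8 Hz, by default), and converted to
instantaneous phase θ(t) ∈ [0, 2π) by the Hilbert transform. Per epoch and
region pair:

- **PLV** — modulus of the mean unit phasor of the phase difference:
  `PLV = |1/N Σₙ exp(i(θx(n) − θy(n)))|`.
- **Phase entropy** — plug-in Shannon entropy of the binned phase
  histogram, with the Scott-rule bin size
  `binsize = 3.49·sd(θ)·N^(−1/3)` and `ceil(2π/binsize)` bins
  (22 bins for a 10-s epoch at 1000 Hz with near-uniform phases).
- **PTE** — directed information flow,
  `PTE(X→Y) = H(θy(t) | θy(t−δ)) − H(θy(t) | θy(t−δ), θx(t−δ))`,
  with the lag δ = N/C set by the mean samples per oscillation (C counts
  the π-crossings of both series).
- **dPTE** — `PTE(X→Y)/(PTE(X→Y)+PTE(Y→X)) − 0.5`, so dPTE > 0 means net
  outflow X→Y and dPTE(X→Y) = −dPTE(Y→X) exactly.

Stacking the per-epoch values yields one fluctuation time course per edge.
Pearson-correlating these columns — dPTE against dPTE, and dPTE against
PLV — exposes *motifs*: bundles of pathways whose information flow
co-fluctuates, and pathways whose flow tracks network connectivity. State
contrasts (e.g. maze-exploration minus rest) difference the mean metric per
edge with t tests, and channel-wise segment-shuffle surrogates provide the
null for observed flow.

## Worked example

`examples/direction_recovery.py` simulates two theta-band oscillators in
which region A pulls region B's phase, and recovers the direction epoch by
epoch:

```
kappa =   0.0 rad/s : mean dPTE(A->B) = +0.0058, epochs with correct sign = 60%
kappa =  10.0 rad/s : mean dPTE(A->B) = +0.1070, epochs with correct sign = 97%
kappa =  25.0 rad/s : mean dPTE(A->B) = +0.1530, epochs with correct sign = 100%
```

With no coupling the sign of dPTE is a coin flip around zero; as the
coupling rate κ grows, the net-outflow estimate grows monotonically and the
10-s epochs identify the true direction essentially always.

`examples/motif_correlation.py` adds the edge-based layer: two edges whose
coupling strengths share a latent factor (loading 0.8) against an
independently fluctuating third edge:

```
designed group   r[dPTE(A->C), dPTE(B->D)] = +0.411  (loading 0.8)
unrelated edge   r[dPTE(A->C), dPTE(E->F)] = -0.079
ground truth     corr of realized coupling strengths = +0.657
max |r| of a group edge with any node-disjoint outside edge = 0.196
```

The designed co-fluctuation is recovered as the top-ranking motif among all
structurally independent edge pairs. The other examples cover Scott-rule
binning (`scott_binning.py`), the segment-shuffle surrogate control
(`surrogate_null.py`), relative power spectra and theta peaks
(`spectral_peaks.py`), and the full staged pipeline with manifest
(`full_pipeline.py`).

## Command line

The `edgeflow` console script is a thin wrapper over the pipeline stages:

```
edgeflow init-config demo.yaml      # starter configuration (small simulation)
edgeflow run --config demo.yaml     # simulate -> ... -> contrast -> surrogate
edgeflow connectivity --config demo.yaml   # or stage by stage
```

Every stage writes CSV/JSON artifacts into the run directory with a
manifest recording the configuration hash and seed; reruns of deterministic
stages are bit-identical.

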