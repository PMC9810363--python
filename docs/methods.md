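# Methods

This note records the models, estimators, parameter choices, and numerical
conventions behind edgeflow, and what the synthetic validation does and
does not establish about real recordings.

## Phase metrics

All metrics operate on the instantaneous phase of a band-limited epoch,
obtained by zero-phase band-pass filtering (forward–backward 4th-order
Butterworth; phase metrics are meaningless under group delay) followed by
the Hilbert transform, wrapped to [0, 2π). Epochs are fixed-length 10-s
windows (configurable), laid down from the start of each behavioural-state
interval with trailing partial windows discarded; sample intervals are
half-open and 0-based. No samples are trimmed at epoch edges: the filter
and Hilbert transients at the boundaries are treated as part of the
method's noise, keeping N equal to the full epoch length (10,000 samples at
1000 Hz), which is what makes the Scott-rule bin count land on 22.

**PLV.** The modulus of the mean unit phasor of the phase difference.
Invariant to a common phase rotation and to positive rescaling of the raw
signal. For N independent uniform phases its expectation is
√π/2 · N^(−1/2) (≈0.0089 at N = 10⁴), the floor against which locking is
judged.

**Phase binning.** The Scott normal-reference rule applied to phases:
binsize = 3.49 · sd(θ) · N^(−1/3), with the ordinary (linear) standard
deviation of the wrapped phases over the whole epoch. The phrase
"standard deviation of the phases" admits several readings (circular sd,
windowed sd); the whole-epoch linear sd is used because it is the only
reading under which near-uniform phases (sd = π/√3 ≈ 1.814) reproduce the
canonical 22-bin resolution for 10-s, 1000-Hz epochs
(binsize ≈ 0.294 rad). The bin count is ceil(2π/binsize) and the edges
divide [0, 2π) uniformly, so the realized width is 2π/n_bins, marginally
below the nominal binsize.

**Entropies.** Plug-in Shannon entropies of the binned histograms, in bits
(base 2). The base cancels in dPTE, which is a ratio; bits are the common
transfer-entropy convention. No bias correction (no Miller–Madow or
finite-size correction) is applied: estimators are the plain plug-in
quantities.

**PTE.** PTE(X→Y) = H(θy(t) | θy(t′)) − H(θy(t) | θy(t′), θx(t′)) with
t′ = t − δ, both conditional entropies estimated from joint histograms over
(θy(t), θy(t′)) and (θy(t), θy(t′), θx(t′)). One binning scheme serves
every variable of a pair: the Scott rule is defined per series, so the pair
uses the mean of the two series' bin sizes. The lag δ = round(N/C) — N the
combined sample count of the two series, C the combined number of upward
π-crossings — is computed per pair per epoch, floored at one sample.
Negative PTE round-off is clamped to zero.

**dPTE.** Computed as (PTE_xy − PTE_yx) / (2·(PTE_xy + PTE_yx)), which is
algebraically PTE_xy/(PTE_xy+PTE_yx) − 0.5 but negates exactly under
argument swap, so the all-pairs dPTE matrix is antisymmetric to the last
bit. When both PTEs are zero there is no flow in either direction and the
value is defined as 0.

## Spectra

Relative power spectra are Welch averages (Hann windows, 50% overlap) of
the z-scored continuous trace, truncated to 0–100 Hz and normalized to unit
sum. The default FFT length of 40,960 samples at 1000 Hz is the only one
that reproduces the 0.0244140625-Hz reporting grid. The normalization of
the raw trace is z-scoring (mean removed, unit variance); relative power
then removes any remaining scale. In-band peaks are located by first
maximum (ties break toward the lower frequency); the default theta search
band is 4–10 Hz because exploration shifts the peak upward.

Continuous traces can be pre-cleaned with `notch_and_detrend`, whose
default stop bands are (0, 0.01) Hz and (48, 52) Hz. The DC-anchored band
is implemented as mean/linear-trend removal: below 0.01 Hz nothing but the
trend is resolvable in these windows and an IIR high-pass at 10⁻⁵ of
Nyquist is numerically degenerate. Interior bands use a zero-phase
4th-order Butterworth band-stop.

## The edge-based motif framework

Per-epoch all-pairs metrics are stacked into an edge × epoch fluctuation
record: 30 signed dPTE columns and 15 PLV columns for six regions. Pearson
correlations between columns (dPTE×dPTE and dPTE×PLV) carry two-sided
p-values from the exact null distribution of r (equivalent to the usual t
test). The dPTE×dPTE matrix is computed once per unordered pair of edges
and expanded by sign, so antisymmetry identities — r = −1 between an edge
and its reverse, r[(a,b),(c,d)] = −r[(b,a),(c,d)] — hold exactly.

**The shared-node confound.** Two edge columns that share a region are
functions of the same channel's phase realization and are therefore
correlated even when all channels are completely independent: in null
simulations (six independent channels, 240 epochs) every shared-node cell
is "significant" at p < 0.05 while node-disjoint cells are exactly
calibrated (r-spread 1/√n, false-positive rate ≈ α). A coupled edge
additionally creates *image* correlations: once A and C phase-lock, the
noise columns dPTE(D→A) and dPTE(D→C) become nearly the same quantity
(|r| up to ~0.8). Motif inference therefore ranks and tests only
node-disjoint edge pairs; `MotifCorrelation.node_disjoint` exposes the
mask. Shared-node and image cells are reported but carry no calibrated
null — they describe the network's structure, not independent evidence of
co-regulation.

Because motif cells within one run share columns, single-run
false-positive counts are overdispersed relative to a binomial even though
each node-disjoint cell's null p is uniform. Calibration is therefore
assessed across independent replicate runs (per-run rates compared to
nominal α with a one-sample t test).

State contrasts use per-edge two-sample (or paired) t tests on the pooled
epochs with raw p-values by default (a Benjamini–Hochberg option exists
but is off, matching how such contrasts are conventionally displayed at
fixed thresholds). Changed-edge counting takes each unordered pair once,
oriented along its net change, with a default magnitude threshold of 0.02
on the mean dPTE difference. Default reporting thresholds: p < 10⁻³ for
contrast network schematics, p < 10⁻¹⁰ (dPTE×dPTE) and p < 10⁻⁷
(dPTE×PLV) for motif displays, p < 10⁻² for transition contrasts; all are
configuration values, and thresholding is a view, never destructive.

**Surrogates.** The null permutes the temporal order of each channel's
10-s segments independently (the analysis epoch is the natural shuffle
unit: it destroys cross-channel alignment while preserving each segment's
spectrum) and recomputes the network-mean metric per shuffle; 1,000
shuffles by default. Random permutations retain fixed points, so roughly
1/n_segments of the true effect leaks into the null mean; with 60 segments
this bias is below 0.003 dPTE units for even the strongest couplings used
here. The dPTE null centres at zero. The PLV null does *not* approach the
iid floor: phases within a 10-s theta segment are autocorrelated, so
chance PLV between independent segments sits near 1/√(cycles) ≈ 0.1–0.2.
Observed values are judged against the surrogate distribution's
percentiles, not against the iid floor.

## The simulator

Each channel is a stochastic phase oscillator: phase advances at the band's
centre frequency plus a slow Ornstein–Uhlenbeck frequency wander
(default sd (high−low)/8 Hz, time constant 2 s) plus white phase jitter
(default 1 rad/√s). A directed coupling pulls the target's phase toward the
source's phase at a fixed sample lag (default 10 samples) with rate κ
(rad/s) via a sine term — a unidirectional noisy Kuramoto/Adler
interaction. The observation is cos(phase) plus additive white Gaussian
noise (default sd 0.5, i.e. −3 dB relative to the unit carrier), keeping
the Hilbert phase recoverable and the noise level interpretable.

Coupling strengths are piecewise-constant per 10-s epoch — the generative
unit matches the analysis unit, so motif correlations have a well-defined
target — with per-epoch strength κ·(1 + sd·latent) clipped at zero; edges
in a comodulation group share a latent factor with the stated loading.
Everything realized is returned as ground truth. A single global seed
drives one generator stream, so a (config, seed) pair replays the entire
experiment bit for bit.

Calibration of "strong" coupling under the default dynamics (established
once on development seeds and then fixed): κ = 10 rad/s yields pairwise
PLV ≈ 0.7 and per-epoch direction detection ≳ 97%; κ = 25 rad/s is
essentially fully locked (PLV ≈ 0.98, detection 100%); mean dPTE is
monotone in κ. Comodulation studies use κ = 10 with per-epoch fluctuation
sd 1.0, where per-epoch dPTE tracks the realized strength at r ≈ 0.6 and a
loading of 0.8 yields within-group dPTE correlations of ≈ 0.2–0.4.

What the simulator emulates: band-limited oscillations, directed phase
coupling with ground-truth orientation, state-scheduled coupling changes,
and designed co-fluctuation of edge strengths. What it does not: volume
conduction / field spread (a major source of spurious zero-lag coupling in
real recordings), 1/f broadband background, cross-frequency structure,
nonstationary artifacts, spiking, or behaviour. Passing the validation
suite therefore shows the estimators recover planted structure under
realistic noise — not that real-tissue confounds are handled.

## Problem sizes and numerics in the validation suite

The test suite and acceptance script run at desk scale: 100 noise epochs
for the binning constants; 60–100 epochs per coupling level for direction
recovery; 60 segments × 200 shuffles for the surrogate control; 20
replicates of 240 epochs for motif recovery; six replicate null runs of
240 epochs for calibration. Degenerate inputs raise typed errors
(constant signals, zero phase variance, oscillation-free series, lags
exceeding the series); dPTE of two zero PTEs is 0 by convention; zero-
variance metric columns yield NaN correlations with a warning rather than
an exception.

## Known limitations

- The PTE estimator is plug-in and biased upward for finite samples;
  dPTE and the surrogate control remove the shared part of this bias, but
  absolute PTE values should not be compared across very different N.
- Band-passed phases are autocorrelated, so per-epoch metric estimates
  have fewer effective degrees of freedom than samples; all inference here
  is across epochs, never within one epoch.
- Shared-node motif cells have no calibrated null (see above); the
  framework quantifies them but draws conclusions only from node-disjoint
  cells.
- The simulator's oscillators share a single carrier band; strongly
  detuned regions would weaken sine coupling and are not modelled.
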