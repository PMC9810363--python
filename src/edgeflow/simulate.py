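"""Synthetic multichannel oscillatory recordings with known directed coupling.

Each channel is a stochastic phase oscillator: its phase advances at the
band's centre frequency, wanders slowly (Ornstein-Uhlenbeck frequency
drift), and diffuses (white phase jitter). A directed coupling pulls the
target's phase toward the source's phase at a fixed sample lag, offset by a
phase delay, via a sine coupling term (a noisy, unidirectional
Kuramoto/Adler interaction):

    theta_tgt[n] += (kappa / fs) * sin(theta_src[n - 1 - lag] - delay - theta_tgt[n - 1])

The observed trace is cos(theta) plus additive white Gaussian noise, so the
Hilbert phase of the band-passed observation recovers theta up to noise.

Coupling strengths are piecewise-constant over analysis epochs (10 s by
default): in epoch k, edge e has realized strength

    kappa_e[k] = max(0, kappa_state * (1 + epoch_coupling_sd * latent_e[k]))

where the per-epoch latents are standard normal. Edges in a comodulation
group share a common latent factor with the stated loading
(latent = loading * z_group + sqrt(1 - loading^2) * own), which induces the
designed co-fluctuation of information flow that the edge-motif analysis
recovers. Everything drawn is recorded in the returned ground truth, and an
identical (config, seed) pair reproduces the recording bit for bit.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sps

from .exceptions import ConfigurationError
from .io import Recording, save_recording

__all__ = [
    "DirectedCoupling",
    "ComodulationGroup",
    "SimulationConfig",
    "CouplingGroundTruth",
    "generate_recording",
    "generate_comotif_recording",
]

DEFAULT_REGIONS = ["mPFC", "ACC", "CeA", "RSC", "PtA", "dHip"]


@dataclass(frozen=True)
class DirectedCoupling:
    """One directed edge of the ground-truth coupling graph.

    ``strength`` maps state label -> kappa in rad/s (the maximum rate at
    which the target's phase is pulled toward the lagged source phase);
    states absent from the map are uncoupled. ``lag_samples`` is the fixed
    sample lag of the interaction, ``phase_delay`` the preferred phase
    offset in radians.
    """

    source: int
    target: int
    strength: dict[str, float] = field(default_factory=dict)
    phase_delay: float = 0.0
    lag_samples: int = 10

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ConfigurationError("self-coupling is not allowed")
        for state, kappa in self.strength.items():
            if not np.isfinite(kappa) or kappa < 0:
                raise ConfigurationError(
                    f"edge {self.source}->{self.target}: kappa for {state!r} "
                    f"must be finite and >= 0, got {kappa}"
                )
        if self.lag_samples < 0:
            raise ConfigurationError("lag_samples must be >= 0")

    @property
    def label(self) -> str:
        return f"{self.source}->{self.target}"


@dataclass(frozen=True)
class ComodulationGroup:
    """A set of directed edges whose per-epoch strengths share a latent factor."""

    edges: tuple[tuple[int, int], ...]
    loading: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", tuple(tuple(e) for e in self.edges))
        if not (0.0 <= self.loading <= 1.0):
            raise ConfigurationError(f"loading must be in [0, 1], got {self.loading}")


@dataclass
class SimulationConfig:
    """Full specification of a synthetic recording.

    Defaults emulate a 6-region recording with three 600-s behavioural
    states (rest, maze exploration, rest again) at 1000 Hz, theta-band
    (4-8 Hz) carriers, and moderate observation noise.
    """

    n_regions: int = 6
    region_names: list[str] | None = None
    sampling_rate: float = 1000.0
    state_schedule: list[tuple[str, float]] = field(
        default_factory=lambda: [("RS", 600.0), ("EPM", 600.0), ("RS2", 600.0)]
    )
    band: tuple[float, float] = (4.0, 8.0)
    coupling_edges: list[DirectedCoupling] = field(default_factory=list)
    epoch_coupling_sd: float = 0.0
    comodulation_groups: list[ComodulationGroup] = field(default_factory=list)
    noise_sd: float = 0.5
    seed: int = 0
    epoch_length: float = 10.0
    # oscillator dynamics: slow OU frequency wander plus white phase jitter
    freq_wander_sd: float | None = None  # Hz; default (high - low) / 8
    freq_wander_tau: float = 2.0  # s
    phase_jitter_sd: float = 1.0  # rad / sqrt(s)

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ConfigurationError("n_regions must be >= 1")
        if self.region_names is None:
            if self.n_regions == len(DEFAULT_REGIONS):
                self.region_names = list(DEFAULT_REGIONS)
            else:
                self.region_names = [f"R{i}" for i in range(self.n_regions)]
        if len(self.region_names) != self.n_regions:
            raise ConfigurationError("region_names length must equal n_regions")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.epoch_length <= 0:
            raise ConfigurationError("epoch_length must be positive")
        low, high = self.band
        if not (0 < low < high < self.sampling_rate / 2):
            raise ConfigurationError(f"band {self.band} invalid for fs={self.sampling_rate}")
        for state, duration in self.state_schedule:
            if duration <= 0:
                raise ConfigurationError(f"state {state!r} has non-positive duration")
        for edge in self.coupling_edges:
            for endpoint in (edge.source, edge.target):
                if not (0 <= endpoint < self.n_regions):
                    raise ConfigurationError(
                        f"edge {edge.label}: region index {endpoint} out of range"
                    )
        known = {(e.source, e.target) for e in self.coupling_edges}
        for group in self.comodulation_groups:
            for pair in group.edges:
                if pair not in known:
                    raise ConfigurationError(
                        f"comodulation group references unknown edge {pair[0]}->{pair[1]}"
                    )
        if self.epoch_coupling_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("epoch_coupling_sd and noise_sd must be >= 0")

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.state_schedule))

    def to_dict(self) -> dict:
        return {
            "n_regions": self.n_regions,
            "region_names": list(self.region_names or []),
            "sampling_rate": self.sampling_rate,
            "state_schedule": [[s, d] for s, d in self.state_schedule],
            "band": list(self.band),
            "coupling_edges": [
                {
                    "source": e.source,
                    "target": e.target,
                    "strength": dict(e.strength),
                    "phase_delay": e.phase_delay,
                    "lag_samples": e.lag_samples,
                }
                for e in self.coupling_edges
            ],
            "epoch_coupling_sd": self.epoch_coupling_sd,
            "comodulation_groups": [
                {"edges": [list(p) for p in g.edges], "loading": g.loading}
                for g in self.comodulation_groups
            ],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "epoch_length": self.epoch_length,
            "freq_wander_sd": self.freq_wander_sd,
            "freq_wander_tau": self.freq_wander_tau,
            "phase_jitter_sd": self.phase_jitter_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["state_schedule"] = [(s, float(dur)) for s, dur in d.get("state_schedule", [])]
        d["band"] = tuple(d.get("band", (4.0, 8.0)))
        d["coupling_edges"] = [
            DirectedCoupling(
                source=e["source"],
                target=e["target"],
                strength=dict(e.get("strength", {})),
                phase_delay=e.get("phase_delay", 0.0),
                lag_samples=e.get("lag_samples", 10),
            )
            for e in d.get("coupling_edges", [])
        ]
        d["comodulation_groups"] = [
            ComodulationGroup(
                edges=tuple(tuple(p) for p in g["edges"]), loading=g["loading"]
            )
            for g in d.get("comodulation_groups", [])
        ]
        return cls(**d)


@dataclass
class CouplingGroundTruth:
    """Realized per-epoch coupling strengths and latent comodulation factors.

    ``strengths`` has one row per epoch x directed edge (columns: epoch,
    state, source, target, kappa); ``latents`` has one row per epoch with
    one column per comodulation group.
    """

    strengths: pd.DataFrame
    latents: pd.DataFrame
    config: SimulationConfig

    def kappa_series(self, source: int, target: int) -> np.ndarray:
        """Realized strength of one edge across epochs."""
        sel = self.strengths[
            (self.strengths.source == source) & (self.strengths.target == target)
        ]
        if sel.empty:
            raise KeyError(f"edge {source}->{target} not in ground truth")
        return sel.sort_values("epoch").kappa.to_numpy()

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.strengths.to_csv(directory / "ground_truth_strengths.csv", index=False)
        self.latents.to_csv(directory / "ground_truth_latents.csv", index=False)
        (directory / "simulation_config.json").write_text(
            json.dumps(self.config.to_dict(), indent=1)
        )


@njit(cache=False)
def _integrate_phases(increments, theta0, src, tgt, lags, delays, kappa_scaled, epoch_samples):
    """Sequential phase update with lagged sine coupling.

    ``increments`` are the uncoupled per-sample phase advances
    (2*pi*f/fs + jitter); ``kappa_scaled`` is (n_edges, n_epochs) already
    divided by the sampling rate.
    """
    n_ch, n_samples = increments.shape
    n_edges = src.shape[0]
    n_epochs = kappa_scaled.shape[1] if n_edges > 0 else 0
    theta = np.empty((n_ch, n_samples))
    for c in range(n_ch):
        theta[c, 0] = theta0[c]
    for n in range(1, n_samples):
        for c in range(n_ch):
            theta[c, n] = theta[c, n - 1] + increments[c, n]
        if n_edges > 0:
            k = n // epoch_samples
            if k >= n_epochs:
                k = n_epochs - 1
            for e in range(n_edges):
                m = n - 1 - lags[e]
                if m >= 0:
                    kap = kappa_scaled[e, k]
                    if kap > 0.0:
                        t = tgt[e]
                        theta[t, n] += kap * np.sin(
                            theta[src[e], m] - delays[e] - theta[t, n - 1]
                        )
    return theta


def _state_at_sample(schedule: list[tuple[str, float]], fs: float):
    """Per-state sample intervals and a lookup of state by sample."""
    intervals = []
    start = 0
    for state, duration in schedule:
        end = start + int(round(duration * fs))
        intervals.append((state, start, end))
        start = end
    return intervals


def _draw_epoch_strengths(config: SimulationConfig, n_epochs: int, states: list[str], rng):
    """Per-epoch realized kappa for every edge, with group comodulation."""
    edges = config.coupling_edges
    n_edges = len(edges)
    groups = config.comodulation_groups
    edge_group = np.full(n_edges, -1, dtype=np.int64)
    loadings = np.zeros(n_edges)
    for g, group in enumerate(groups):
        for pair in group.edges:
            for e, edge in enumerate(edges):
                if (edge.source, edge.target) == pair:
                    edge_group[e] = g
                    loadings[e] = group.loading
    group_z = rng.standard_normal((n_epochs, len(groups))) if groups else np.zeros((n_epochs, 0))
    own_z = rng.standard_normal((n_epochs, n_edges)) if n_edges else np.zeros((n_epochs, 0))
    kappa = np.zeros((n_edges, n_epochs))
    for e, edge in enumerate(edges):
        if edge_group[e] >= 0:
            lam = loadings[e]
            latent = lam * group_z[:, edge_group[e]] + np.sqrt(1.0 - lam**2) * own_z[:, e]
        else:
            latent = own_z[:, e]
        base = np.array([edge.strength.get(state, 0.0) for state in states])
        kappa[e] = np.maximum(0.0, base * (1.0 + config.epoch_coupling_sd * latent))
    return kappa, group_z


def generate_recording(config: SimulationConfig) -> tuple[Recording, CouplingGroundTruth]:
    """Simulate a recording with known directed phase coupling.

    Returns the observed recording (cos(phase) + noise, unit carrier
    amplitude) and the ground truth of realized per-epoch coupling strengths
    and latent factors. Identical (config, seed) gives identical output.
    """
    fs = config.sampling_rate
    n_samples = int(round(config.total_duration * fs))
    epoch_samples = int(round(config.epoch_length * fs))
    if n_samples < epoch_samples:
        raise ConfigurationError(
            f"total duration {config.total_duration} s shorter than one epoch "
            f"({config.epoch_length} s)"
        )
    n_epochs = n_samples // epoch_samples
    n_ch = config.n_regions
    rng = np.random.default_rng(config.seed)

    intervals = _state_at_sample(config.state_schedule, fs)
    epoch_states = []
    for k in range(n_epochs):
        sample = k * epoch_samples
        state = next(st for st, a, b in intervals if a <= sample < b)
        epoch_states.append(state)

    low, high = config.band
    f0 = 0.5 * (low + high)
    wander_sd = config.freq_wander_sd if config.freq_wander_sd is not None else (high - low) / 8.0
    dt = 1.0 / fs

    # OU frequency wander, one AR(1) stream per channel
    a = np.exp(-dt / config.freq_wander_tau)
    innov_sd = wander_sd * np.sqrt(1.0 - a * a)
    wander_noise = rng.standard_normal((n_ch, n_samples)) * innov_sd
    wander = sps.lfilter([1.0], [1.0, -a], wander_noise, axis=1)
    jitter = rng.standard_normal((n_ch, n_samples)) * (config.phase_jitter_sd * np.sqrt(dt))
    increments = 2.0 * np.pi * (f0 + wander) * dt + jitter
    del wander, wander_noise, jitter
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)

    kappa, group_z = _draw_epoch_strengths(config, n_epochs, epoch_states, rng)

    edges = config.coupling_edges
    src = np.array([e.source for e in edges], dtype=np.int64)
    tgt = np.array([e.target for e in edges], dtype=np.int64)
    lags = np.array([e.lag_samples for e in edges], dtype=np.int64)
    delays = np.array([e.phase_delay for e in edges], dtype=np.float64)
    if edges:
        theta = _integrate_phases(
            increments, theta0, src, tgt, lags, delays, kappa / fs, epoch_samples
        )
    else:
        theta = np.cumsum(increments, axis=1)
        theta += theta0[:, None] - theta[:, :1]
    del increments

    observed = np.cos(theta)
    if config.noise_sd > 0:
        observed += rng.standard_normal((n_ch, n_samples)) * config.noise_sd
    del theta

    recording = Recording(
        observed,
        fs,
        list(config.region_names or []),
        [(st, a, min(b, n_samples)) for st, a, b in intervals],
    )
    rows = []
    for k in range(n_epochs):
        for e, edge in enumerate(edges):
            rows.append(
                {
                    "epoch": k,
                    "state": epoch_states[k],
                    "source": edge.source,
                    "target": edge.target,
                    "kappa": kappa[e, k],
                }
            )
    strengths = pd.DataFrame(rows, columns=["epoch", "state", "source", "target", "kappa"])
    latents = pd.DataFrame(
        group_z, columns=[f"group_{g}" for g in range(group_z.shape[1])]
    )
    latents.insert(0, "epoch", np.arange(n_epochs))
    truth = CouplingGroundTruth(strengths=strengths, latents=latents, config=config)
    return recording, truth


def generate_comotif_recording(config: SimulationConfig) -> tuple[Recording, CouplingGroundTruth]:
    """Simulate a recording whose edge strengths co-fluctuate by design.

    Requires at least one comodulation group of two or more edges, each of
    which must be coupled (kappa > 0) in at least one state; otherwise
    identical to :func:`generate_recording`.
    """
    if not any(len(g.edges) >= 2 for g in config.comodulation_groups):
        raise ConfigurationError(
            "comotif generation needs a comodulation group with >= 2 edges"
        )
    by_pair = {(e.source, e.target): e for e in config.coupling_edges}
    for group in config.comodulation_groups:
        for pair in group.edges:
            edge = by_pair[pair]
            if all(k == 0.0 for k in edge.strength.values()) or not edge.strength:
                raise ConfigurationError(
                    f"comodulated edge {pair[0]}->{pair[1]} has zero strength in all states"
                )
    return generate_recording(config)


def save_simulation(
    recording: Recording, truth: CouplingGroundTruth, directory: str | Path
) -> Path:
    """Write the recording container plus ground-truth CSVs and config sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_recording(recording, directory / "recording.h5", format="container")
    truth.save(directory)
    return directory
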