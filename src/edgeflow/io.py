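"""Recording containers, epoching, filtering, and instantaneous phase.

A :class:`Recording` is a channels x samples matrix of continuous field
potentials at a fixed sampling rate, with one region label per channel and a
table of behavioural-state intervals (half-open, in samples). Recordings
round-trip through an HDF5 container or a delimited-text + JSON-sidecar pair.

The analysis unit is the :class:`Epoch`: a fixed-length, single-channel
window cut from one state. Epochs are band-pass filtered with a zero-phase
(forward-backward) 4th-order Butterworth filter — phase metrics are
meaningless under group delay — and converted to instantaneous phase in
[0, 2*pi) via the Hilbert transform.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import (
    DegenerateSignalError,
    FormatError,
    ValidationError,
)

__all__ = [
    "Band",
    "BAND_TABLE",
    "Recording",
    "Epoch",
    "PhaseSeries",
    "load_recording",
    "load_state_annotations",
    "save_recording",
    "segment_epochs",
    "extract_transition_epochs",
    "notch_and_detrend",
    "bandpass",
    "bandpass_filter",
    "hilbert_phase",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class Band:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValidationError(
                f"band {self.name!r}: need 0 < low < high, got ({self.low}, {self.high})"
            )


#: Default physiological band table. Only the theta edges are canonical in the
#: rodent literature; the others follow common convention and are overridable.
BAND_TABLE: dict[str, Band] = {
    "delta": Band("delta", 1.0, 4.0),
    "theta": Band("theta", 4.0, 8.0),
    "alpha": Band("alpha", 8.0, 12.0),
    "beta": Band("beta", 12.0, 30.0),
    "gamma": Band("gamma", 30.0, 80.0),
}


@dataclass
class Recording:
    """Multichannel continuous recording with state annotations.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Continuous voltage traces, arbitrary units.
    sampling_rate : float
        Acquisition rate in Hz.
    region_labels : sequence of str
        One label per channel.
    state_intervals : list of (state, start_sample, end_sample)
        Half-open sample intervals, 0-based. Intervals of the same state
        must not overlap.
    """

    signal: np.ndarray
    sampling_rate: float
    region_labels: list[str]
    state_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] < 1:
            raise ValidationError("signal must be a (n_channels, n_samples) matrix")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if len(self.region_labels) != self.n_channels:
            raise ValidationError("one region label per channel required")
        n = self.n_samples
        by_state: dict[str, list[tuple[int, int]]] = {}
        for state, start, end in self.state_intervals:
            if not (0 <= start < end <= n):
                raise ValidationError(
                    f"state interval {state!r} [{start}, {end}) outside [0, {n})"
                )
            by_state.setdefault(state, []).append((int(start), int(end)))
        for state, ivals in by_state.items():
            ivals.sort()
            for (_, e0), (s1, _) in zip(ivals, ivals[1:]):
                if s1 < e0:
                    raise ValidationError(f"overlapping intervals for state {state!r}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Total duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def states(self) -> list[str]:
        """State labels in order of first appearance."""
        seen: list[str] = []
        for state, _, _ in self.state_intervals:
            if state not in seen:
                seen.append(state)
        return seen

    def intervals_of(self, state: str) -> list[tuple[int, int]]:
        ivals = [(s, e) for st, s, e in self.state_intervals if st == state]
        if not ivals:
            raise LookupError(f"state {state!r} not present in recording")
        return sorted(ivals)


@dataclass
class Epoch:
    """One fixed-length window of one channel."""

    signal: np.ndarray
    sampling_rate: float
    region: str
    state: str
    epoch_index: int

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64).ravel()

    @property
    def n_samples(self) -> int:
        return self.signal.size


@dataclass
class PhaseSeries:
    """Instantaneous phase of one epoch, wrapped to [0, 2*pi)."""

    phase: np.ndarray
    sampling_rate: float
    region: str
    state: str
    epoch_index: int

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=np.float64).ravel()

    @property
    def n_samples(self) -> int:
        return self.phase.size


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

def save_recording(rec: Recording, path: str | Path, format: str = "container") -> Path:
    """Write a recording to disk.

    ``container`` is an HDF5 file (bit-exact round trip); ``delimited`` is a
    CSV with one column per channel plus a ``<path>.json`` metadata sidecar.
    """
    path = Path(path)
    if format == "container":
        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=rec.signal)
            f.attrs["sampling_rate"] = rec.sampling_rate
            f.create_dataset(
                "region_labels",
                data=np.array(rec.region_labels, dtype=h5py.string_dtype()),
            )
            states = np.array(
                [s for s, _, _ in rec.state_intervals], dtype=h5py.string_dtype()
            )
            bounds = np.array(
                [[a, b] for _, a, b in rec.state_intervals], dtype=np.int64
            ).reshape(-1, 2)
            f.create_dataset("state_labels", data=states)
            f.create_dataset("state_bounds", data=bounds)
    elif format == "delimited":
        pd.DataFrame(rec.signal.T, columns=rec.region_labels).to_csv(path, index=False)
        sidecar = {
            "sampling_rate": rec.sampling_rate,
            "region_labels": list(rec.region_labels),
            "state_intervals": [[s, int(a), int(b)] for s, a, b in rec.state_intervals],
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValidationError(f"unknown format {format!r}")
    return path


def load_recording(path: str | Path, format: str = "container") -> Recording:
    """Read a recording written by :func:`save_recording`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "container":
        with h5py.File(path, "r") as f:
            if "sampling_rate" not in f.attrs:
                raise FormatError("container missing sampling_rate attribute")
            signal = f["signal"][()]
            rate = float(f.attrs["sampling_rate"])
            labels = [s.decode() if isinstance(s, bytes) else s for s in f["region_labels"][()]]
            states = [s.decode() if isinstance(s, bytes) else s for s in f["state_labels"][()]]
            bounds = f["state_bounds"][()]
            intervals = [
                (st, int(a), int(b)) for st, (a, b) in zip(states, bounds)
            ]
        return Recording(signal, rate, labels, intervals)
    if format == "delimited":
        sidecar_path = Path(str(path) + ".json")
        if not sidecar_path.exists():
            raise FormatError(f"missing metadata sidecar {sidecar_path}")
        meta = json.loads(sidecar_path.read_text())
        if "sampling_rate" not in meta:
            raise FormatError("sidecar missing sampling_rate")
        try:
            frame = pd.read_csv(path)
        except pd.errors.ParserError as exc:  # ragged rows
            raise FormatError(f"malformed delimited recording: {exc}") from exc
        labels = list(meta.get("region_labels", frame.columns))
        if len(labels) != frame.shape[1]:
            raise FormatError(
                f"{len(labels)} channel labels but {frame.shape[1]} signal columns"
            )
        if frame.isna().any().any():
            raise FormatError("ragged or missing samples in delimited recording")
        intervals = [
            (str(s), int(a), int(b)) for s, a, b in meta.get("state_intervals", [])
        ]
        return Recording(frame.to_numpy().T, float(meta["sampling_rate"]), labels, intervals)
    raise ValidationError(f"unknown format {format!r}")


def load_state_annotations(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a state/transition annotation CSV with columns state,start_sample,end_sample."""
    frame = pd.read_csv(path)
    required = {"state", "start_sample", "end_sample"}
    if not required.issubset(frame.columns):
        raise FormatError(f"annotation CSV must have columns {sorted(required)}")
    return [
        (str(r.state), int(r.start_sample), int(r.end_sample))
        for r in frame.itertuples()
    ]


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def segment_epochs(
    rec: Recording, epoch_length: float, state: str
) -> dict[str, list[Epoch]]:
    """Cut consecutive non-overlapping fixed-length epochs from one state.

    Windows are laid down from the start of each of the state's intervals;
    a trailing partial window is discarded. Returns a mapping from region
    label to that channel's epochs, indexed in temporal order.
    """
    if epoch_length <= 0:
        raise ValidationError("epoch_length must be positive")
    win = int(round(epoch_length * rec.sampling_rate))
    out: dict[str, list[Epoch]] = {label: [] for label in rec.region_labels}
    index = 0
    for start, end in rec.intervals_of(state):
        n_win = (end - start) // win
        for k in range(n_win):
            a = start + k * win
            for ch, label in enumerate(rec.region_labels):
                out[label].append(
                    Epoch(rec.signal[ch, a : a + win], rec.sampling_rate, label, state, index)
                )
            index += 1
    return out


def extract_transition_epochs(
    rec: Recording, transitions: Sequence[tuple[int, int]]
) -> dict[str, list[Epoch]]:
    """Cut variable-length epochs (state label ``"transition"``) from annotated intervals."""
    out: dict[str, list[Epoch]] = {label: [] for label in rec.region_labels}
    for index, (start, end) in enumerate(transitions):
        if end <= start:
            raise ValidationError(f"transition interval [{start}, {end}) is empty")
        if not (0 <= start and end <= rec.n_samples):
            raise ValidationError(
                f"transition interval [{start}, {end}) outside recording of "
                f"{rec.n_samples} samples"
            )
        for ch, label in enumerate(rec.region_labels):
            out[label].append(
                Epoch(rec.signal[ch, start:end], rec.sampling_rate, label, "transition", index)
            )
    return out


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _sos_bandpass(low: float, high: float, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if high >= nyq:
        raise ValidationError(f"band edge {high} Hz at or above Nyquist ({nyq} Hz)")
    return sps.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")


def notch_and_detrend(
    signal: np.ndarray,
    sampling_rate: float,
    stop_bands: Sequence[tuple[float, float]] = ((0.0, 0.01), (48.0, 52.0)),
) -> np.ndarray:
    """Remove slow drift and line-frequency bands from a continuous trace.

    A stop band whose lower edge is (near) DC is implemented as mean removal
    plus linear detrending followed by a zero-phase high-pass at the band's
    upper edge; interior stop bands use a zero-phase 4th-order Butterworth
    band-stop.
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    nyq = sampling_rate / 2.0
    for low, high in stop_bands:
        if not (0 <= low < high):
            raise ValidationError(f"invalid stop band ({low}, {high})")
        if high >= nyq:
            raise ValidationError(f"stop band ({low}, {high}) reaches Nyquist ({nyq} Hz)")
    if x.size == 0 or np.ptp(x) == 0.0:
        return np.zeros_like(x)
    for low, high in stop_bands:
        # a DC-anchored band is drift removal: below ~0.01 Hz nothing but the
        # mean and slow trend is resolvable in these windows, and an IIR
        # high-pass at 1e-5 of Nyquist is numerically degenerate
        if low < 1.0 / (x.size / sampling_rate):
            x = sps.detrend(x, type="linear")
        else:
            sos = sps.butter(2, [low, high], btype="bandstop", fs=sampling_rate, output="sos")
            x = sps.sosfiltfilt(sos, x)
    return x


def bandpass_filter(signal: np.ndarray, sampling_rate: float, band: Band) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass of a raw vector."""
    sos = _sos_bandpass(band.low, band.high, sampling_rate)
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=np.float64).ravel())


def bandpass(epoch: Epoch, band: Band) -> Epoch:
    """Band-pass an epoch with zero group delay in the passband."""
    filtered = bandpass_filter(epoch.signal, epoch.sampling_rate, band)
    return replace(epoch, signal=filtered)


# ---------------------------------------------------------------------------
# Instantaneous phase
# ---------------------------------------------------------------------------

def hilbert_phase(epoch: Epoch) -> PhaseSeries:
    """Instantaneous phase of a band-limited epoch, wrapped to [0, 2*pi).

    The caller is responsible for band-limiting the epoch first; the phase of
    a broadband signal is not interpretable. Positive rescaling of the input
    leaves the phase unchanged.
    """
    x = epoch.signal
    if x.size < 2 or np.ptp(x) == 0.0:
        raise DegenerateSignalError(
            "constant signal has no instantaneous phase"
        )
    analytic = sps.hilbert(x)
    phase = np.mod(np.angle(analytic), TWO_PI)
    return PhaseSeries(phase, epoch.sampling_rate, epoch.region, epoch.state, epoch.epoch_index)
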