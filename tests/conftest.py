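"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from edgeflow import Band, Epoch, PhaseSeries

TWO_PI = 2.0 * np.pi


@pytest.fixture
def theta() -> Band:
    return Band("theta", 4.0, 8.0)


def sinusoid_phase(freq: float, duration: float, fs: float) -> np.ndarray:
    """Wrapped phase ramp of a pure sinusoid: (2*pi*f*t) mod 2*pi."""
    t = np.arange(int(round(duration * fs))) / fs
    return np.mod(TWO_PI * freq * t, TWO_PI)


def make_phase_series(phase: np.ndarray, region: str = "A", state: str = "RS",
                      epoch_index: int = 0, fs: float = 1000.0) -> PhaseSeries:
    return PhaseSeries(phase, fs, region, state, epoch_index)


def make_epoch(signal: np.ndarray, region: str = "A", state: str = "RS",
               epoch_index: int = 0, fs: float = 1000.0) -> Epoch:
    return Epoch(signal, fs, region, state, epoch_index)


# ---------------------------------------------------------------------------
# Brute-force histogram oracles, independent of the implementation path:
# entropies computed with np.histogram / np.histogramdd and the direct
# conditional-entropy formula H(B|A) = -sum p(a,b) log2(p(a,b)/p(a)).
# ---------------------------------------------------------------------------

def entropy_bits_oracle(phases: np.ndarray, edges: np.ndarray) -> float:
    counts, _ = np.histogram(phases, bins=edges)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def conditional_entropy_oracle(b: np.ndarray, conditions: list[np.ndarray],
                               edges: np.ndarray) -> float:
    """H(B | A1, A2, ...) from an explicit joint histogram."""
    sample = np.column_stack(conditions + [b])
    joint, _ = np.histogramdd(sample, bins=[edges] * sample.shape[1])
    pj = joint / joint.sum()
    pa = pj.sum(axis=-1)  # marginal over B (last axis)
    pa_b = np.broadcast_to(pa[..., None], pj.shape)
    mask = pj > 0
    return float(-np.sum(pj[mask] * np.log2(pj[mask] / pa_b[mask])))


def pte_oracle(px: np.ndarray, py: np.ndarray, delta: int, edges: np.ndarray) -> float:
    y_now, y_past, x_past = py[delta:], py[:-delta], px[:-delta]
    return conditional_entropy_oracle(y_now, [y_past], edges) - conditional_entropy_oracle(
        y_now, [y_past, x_past], edges
    )
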