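"""Relative power spectra and theta peak detection.

Spectra are Welch averages of the z-scored continuous trace, truncated to
0-100 Hz and normalized to unit sum, so each value is the fraction of
0-100 Hz power at that frequency. The default FFT length of 40,960 samples
at 1000 Hz yields the 0.0244140625-Hz grid spacing used for reporting.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import ValidationError
from .io import Band

__all__ = ["Spectrum", "ThetaPeak", "power_spectrum", "theta_peak", "DEFAULT_NFFT"]

#: FFT window length reproducing a 1000/40960 ~ 0.0244 Hz grid at 1000 Hz.
DEFAULT_NFFT = 40960

#: Upper edge of the reported spectrum in Hz.
F_MAX = 100.0


@dataclass
class Spectrum:
    """Relative power on a uniform frequency grid over 0-100 Hz."""

    frequencies: np.ndarray
    relative_power: np.ndarray
    region: str = ""
    state: str = ""

    @property
    def grid_spacing(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def to_frame(self):
        """Tabular view (frequency, relative_power) for CSV export."""
        import pandas as pd

        return pd.DataFrame(
            {"frequency": self.frequencies, "relative_power": self.relative_power}
        )


@dataclass(frozen=True)
class ThetaPeak:
    """Location and height of the maximum relative power inside a band."""

    peak_frequency: float
    peak_relative_power: float


def power_spectrum(
    signal: np.ndarray,
    sampling_rate: float,
    nfft: int = DEFAULT_NFFT,
    region: str = "",
    state: str = "",
) -> Spectrum:
    """Relative power spectrum of a z-scored trace, 0-100 Hz, unit sum.

    Welch averaging with Hann windows of ``nfft`` samples and 50% overlap.
    Rescaling the input leaves the result unchanged (the trace is z-scored
    first, and relative power normalizes away the remaining scale).
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    if x.size < nfft:
        raise ValidationError(
            f"signal of {x.size} samples shorter than FFT window ({nfft})"
        )
    sd = x.std()
    if sd == 0.0:
        raise ValidationError("constant signal has no spectrum")
    z = (x - x.mean()) / sd
    freqs, psd = sps.welch(
        z, fs=sampling_rate, window="hann", nperseg=nfft, noverlap=nfft // 2
    )
    keep = freqs <= F_MAX
    freqs, psd = freqs[keep], psd[keep]
    total = psd.sum()
    if total == 0.0:
        raise ValidationError("zero total power in 0-100 Hz")
    return Spectrum(freqs, psd / total, region=region, state=state)


def theta_peak(spec: Spectrum, band: Band) -> ThetaPeak:
    """Frequency and value of the maximum relative power inside a band.

    Ties are broken toward the lower frequency; a flat in-band spectrum
    therefore returns the first in-band grid point.
    """
    mask = (spec.frequencies >= band.low) & (spec.frequencies <= band.high)
    if not mask.any():
        raise ValidationError(
            f"band ({band.low}, {band.high}) Hz contains no grid points"
        )
    in_band = spec.relative_power[mask]
    in_freq = spec.frequencies[mask]
    k = int(np.argmax(in_band))  # argmax returns the first (lowest-frequency) maximum
    return ThetaPeak(peak_frequency=float(in_freq[k]), peak_relative_power=float(in_band[k]))
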