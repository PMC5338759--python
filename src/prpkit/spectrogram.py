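"""Peripheral auditory model: cochlear filterbank -> hair cell -> lateral
inhibition -> envelope, yielding the auditory spectrogram s(f, t).

The three stages mirror the classic early-auditory models: (1) a bank of
asymmetric bandpass filters equally spaced on a log-frequency axis, (2) hair-
cell transduction as a compressive nonlinearity followed by a membrane
low-pass, and (3) a lateral inhibitory network realized as a first-order
derivative across the spectral (channel) axis with half-wave rectification.
The final per-channel envelope is low-passed and sampled at ``frame_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .types import AuditorySpectrogram

__all__ = [
    "FilterbankParams",
    "BandSignals",
    "cochlear_filterbank",
    "hair_cell_stage",
    "lateral_inhibition",
    "envelope",
    "compute_auditory_spectrogram",
]


@dataclass(frozen=True)
class FilterbankParams:
    """Cochlear filterbank configuration.

    ``asymmetry`` is the ratio of the low-side to the high-side filter skirt
    width (in octaves); values > 1 make the high-frequency skirt steeper, as
    in cochlear tuning curves.
    """

    n_channels: int = 128
    f_min: float = 80.0
    f_max: float = 8000.0
    asymmetry: float = 2.0
    bandwidth_octaves: float = 0.35  # high-side Gaussian sigma in octaves
    hair_cell_cutoff: float = 2000.0
    frame_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if not 0 < self.f_min < self.f_max:
            raise ValueError("need 0 < f_min < f_max")
        if self.asymmetry <= 0 or self.bandwidth_octaves <= 0:
            raise ValueError("asymmetry and bandwidth must be positive")

    @property
    def center_frequencies(self) -> np.ndarray:
        """Strictly increasing, equally spaced in log-frequency."""
        return np.geomspace(self.f_min, self.f_max, self.n_channels)


@dataclass
class BandSignals:
    """Per-channel band signals at the audio sampling rate."""

    values: np.ndarray  # channel x sample
    fs: float
    center_frequencies: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def _filter_magnitude(freqs: np.ndarray, fc: float, params: FilterbankParams) -> np.ndarray:
    """Asymmetric magnitude response in log-frequency: Gaussian skirts with a
    steeper high side (sigma_high = sigma_low / asymmetry)."""
    with np.errstate(divide="ignore"):
        x = np.log2(np.maximum(freqs, 1e-12) / fc)
    sig_hi = params.bandwidth_octaves
    sig_lo = params.bandwidth_octaves * params.asymmetry
    mag = np.where(
        x <= 0,
        np.exp(-0.5 * (x / sig_lo) ** 2),
        np.exp(-0.5 * (x / sig_hi) ** 2),
    )
    mag[freqs <= 0] = 0.0
    return mag


def cochlear_filterbank(
    wave: np.ndarray, fs: float, params: FilterbankParams | None = None
) -> BandSignals:
    """Decompose a mono waveform into log-spaced asymmetric frequency bands.

    Zero-phase FFT filtering: each channel's spectrum is the input spectrum
    weighted by the channel's magnitude response.
    """
    params = params or FilterbankParams()
    wave = np.asarray(wave, dtype=float)
    if wave.ndim != 1:
        raise ValueError("waveform must be mono (1-D)")
    if fs < 2 * params.f_max:
        raise ValueError(f"fs = {fs} Hz is below twice f_max = {params.f_max} Hz")
    cfs = params.center_frequencies
    spec = np.fft.rfft(wave)
    freqs = np.fft.rfftfreq(wave.size, 1 / fs)
    bands = np.empty((params.n_channels, wave.size))
    for j, fc in enumerate(cfs):
        bands[j] = np.fft.irfft(spec * _filter_magnitude(freqs, fc, params), n=wave.size)
    return BandSignals(bands, fs, cfs)


def _smoothing_kernel(fs: float, cutoff: float) -> np.ndarray:
    """Non-negative Hann smoothing kernel with unit area.

    A non-negative impulse response keeps the hair-cell stage monotone
    (pointwise-larger inputs map to pointwise larger-or-equal outputs). The
    kernel length is ``fs / cutoff`` samples so its first spectral null sits
    near the configured cutoff.
    """
    m = max(int(round(fs / cutoff)), 1)
    if m < 2:
        return np.ones(1)
    k = np.hanning(m + 2)[1:-1]
    return k / k.sum()


def hair_cell_stage(bands: BandSignals, params: FilterbankParams | None = None) -> BandSignals:
    """Cube-root compression followed by a membrane low-pass filter."""
    params = params or FilterbankParams()
    x = np.asarray(bands.values, dtype=float)
    compressed = np.cbrt(x)
    if params.hair_cell_cutoff >= bands.fs / 2:
        out = compressed
    else:
        kernel = _smoothing_kernel(bands.fs, params.hair_cell_cutoff)
        out = fftconvolve(compressed, kernel[None, :], mode="same", axes=1)
    return BandSignals(out, bands.fs, bands.center_frequencies)


def lateral_inhibition(bands: BandSignals) -> BandSignals:
    """First difference along the spectral axis, then half-wave rectification.

    The derivative uses a replicated edge (channel 0 differenced against
    itself), so a spectrally flat input yields exactly zero output and the
    channel count is preserved.
    """
    if bands.n_channels < 2:
        raise ValueError("lateral inhibition requires at least 2 channels")
    x = bands.values
    d = np.empty_like(x)
    d[0] = 0.0
    d[1:] = x[1:] - x[:-1]
    return BandSignals(np.maximum(d, 0.0), bands.fs, bands.center_frequencies)


def envelope(bands: BandSignals, frame_rate: float) -> AuditorySpectrogram:
    """Rectify, low-pass at the frame Nyquist, and sample at ``frame_rate``.

    Output has ``ceil(duration * frame_rate)`` frames.
    """
    x = np.maximum(bands.values, 0.0)
    kernel = _smoothing_kernel(bands.fs, frame_rate / 2)
    sm = fftconvolve(x, kernel[None, :], mode="same", axes=1)
    sm = np.maximum(sm, 0.0)  # clip fft round-off
    duration = x.shape[1] / bands.fs
    n_frames = int(np.ceil(duration * frame_rate))
    idx = np.minimum((np.arange(n_frames) / frame_rate * bands.fs).astype(int), x.shape[1] - 1)
    return AuditorySpectrogram(sm[:, idx], bands.center_frequencies, frame_rate)


def compute_auditory_spectrogram(
    wave: np.ndarray, fs: float, params: FilterbankParams | None = None
) -> AuditorySpectrogram:
    """Full deterministic chain: filterbank -> hair cell -> lateral inhibition
    -> envelope at ``params.frame_rate``."""
    params = params or FilterbankParams()
    bands = cochlear_filterbank(wave, fs, params)
    bands = hair_cell_stage(bands, params)
    bands = lateral_inhibition(bands)
    return envelope(bands, params.frame_rate)
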