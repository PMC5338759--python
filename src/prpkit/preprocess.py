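"""EEG preprocessing: zero-phase bandpass, per-channel normalization,
amplitude-based epoch rejection, utterance-onset exclusion, and the PRP
band-power diagnostic used to justify the 2-15 Hz analysis band.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import firwin, fftconvolve, resample_poly

from .types import EEGRecording, EpochSet, PhonemeAlignment, RejectionMask

__all__ = [
    "bandpass_filter",
    "zscore_channels",
    "reject_artifact_epochs",
    "exclude_utterance_onset_tokens",
    "prp_band_power",
    "resample_recording",
]


def _design_fir(fs: float, low: float, high: float, transition: float) -> np.ndarray:
    # Hamming windowed-sinc: transition width ~ 3.3 / numtaps (normalized),
    # so numtaps ~ 3.3 * fs / transition; forced odd for a symmetric type-I FIR.
    numtaps = int(np.ceil(3.3 * fs / transition))
    numtaps += 1 - numtaps % 2
    return firwin(numtaps, [low, high], pass_zero=False, fs=fs, window="hamming")


def bandpass_filter(
    rec: EEGRecording,
    low: float = 2.0,
    high: float = 15.0,
    transition: float = 0.5,
) -> EEGRecording:
    """Zero-phase FIR bandpass (default 2-15 Hz).

    A symmetric (linear-phase) windowed-sinc kernel applied once with its
    group delay compensated is exactly zero-phase; edges are handled by
    reflection padding. ``transition`` (Hz) sets the kernel length and hence
    the steepness at the 2 Hz edge.
    """
    if not 0 < low < high < rec.fs / 2:
        raise ValueError(f"invalid band ({low}, {high}) for fs = {rec.fs}")
    kernel = _design_fir(rec.fs, low, high, transition)
    half = kernel.size // 2
    if rec.n_samples <= half:
        raise ValueError(
            f"recording too short ({rec.n_samples} samples) for the "
            f"{kernel.size}-tap zero-phase kernel; widen `transition` or record longer"
        )
    x = rec.values
    padded = np.concatenate([x[:, half:0:-1], x, x[:, -2 : -half - 2 : -1]], axis=1)
    y = fftconvolve(padded, kernel[None, :], mode="same", axes=1)[:, half:-half]
    return rec.copy_with(y)


def zscore_channels(rec: EEGRecording) -> EEGRecording:
    """Normalize each channel to zero mean, unit variance.

    Constant (zero-variance) channels cannot be normalized; they are dropped
    with a warning.
    """
    x = rec.values
    mean = x.mean(axis=1, keepdims=True)
    std = x.std(axis=1, keepdims=True)
    flat = std[:, 0] == 0
    if np.any(flat):
        bad = [rec.electrode_labels[i] for i in np.flatnonzero(flat)]
        warnings.warn(f"dropping constant channels: {bad}", stacklevel=2)
        keepers = ~flat
        return EEGRecording(
            (x[keepers] - mean[keepers]) / std[keepers],
            rec.fs,
            [l for l, k in zip(rec.electrode_labels, keepers) if k],
            rec.reference,
        )
    return rec.copy_with((x - mean) / std)


def reject_artifact_epochs(epochs: EpochSet, threshold: float = 10.0) -> RejectionMask:
    """Drop an epoch iff any sample of any electrode exceeds ``threshold``
    in magnitude (z-units; data are assumed z-scored upstream)."""
    if len(epochs) == 0:
        return RejectionMask(np.zeros(0, dtype=bool), threshold)
    peak = np.max(np.abs(epochs.epochs), axis=(1, 2))
    return RejectionMask(peak <= threshold, threshold)


def exclude_utterance_onset_tokens(
    alignment: PhonemeAlignment, window: float = 0.5
) -> PhonemeAlignment:
    """Remove tokens starting within ``window`` seconds of their utterance's
    first token onset (suppresses the dominant utterance-onset response)."""
    if window < 0:
        raise ValueError("window must be non-negative")
    first: dict[int, float] = {}
    for tok in alignment:
        first.setdefault(tok.utterance, tok.onset)
    keep = [tok.onset - first[tok.utterance] >= window for tok in alignment]
    return alignment.subset(keep)


def prp_band_power(
    prp_series: np.ndarray, fs: float, f_max: float = 40.0
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Spectral power of an average PRP trace.

    Returns ``(freqs, power, peak_freq)`` up to ``f_max``; ``peak_freq`` is
    ``None`` when the largest bin does not rise above 10x the mean of the
    remaining bins (for a flat spectrum the expected max/mean ratio is only
    ~log n, so this flags "no clear peak" reliably). Used to locate the
    PRP's dominant rhythm (~8 Hz, the syllabic rate).
    """
    x = np.asarray(prp_series, dtype=float)
    if x.ndim != 1:
        raise ValueError("prp_series must be 1-D")
    if x.size < fs / 2:  # shorter than one cycle of 2 Hz
        raise ValueError("series too short for spectral analysis of the 2 Hz edge")
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2
    freqs = np.fft.rfftfreq(x.size, 1 / fs)
    sel = freqs <= f_max
    freqs, spec = freqs[sel], spec[sel]
    if not np.any(spec > 0):
        return freqs, spec, None
    peak_i = int(np.argmax(spec))
    others = np.delete(spec, peak_i)
    clear = others.mean() == 0 or spec[peak_i] > 10 * others.mean()
    return freqs, spec, float(freqs[peak_i]) if clear else None


def resample_recording(rec: EEGRecording, fs_out: float) -> EEGRecording:
    """Polyphase resampling to the shared analysis grid (default 1 kHz in the
    full pipeline, so EEG lags align with spectrogram frames)."""
    if fs_out <= 0:
        raise ValueError("target rate must be positive")
    if fs_out == rec.fs:
        return rec
    from fractions import Fraction

    frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
    y = resample_poly(rec.values, frac.numerator, frac.denominator, axis=1)
    return EEGRecording(y, fs_out, list(rec.electrode_labels), rec.reference)
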