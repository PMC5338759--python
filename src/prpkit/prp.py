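"""Phoneme-related potentials: epoch extraction and category averaging.

The PRP of category k at electrode e and lag tau is the mean over that
category's kept instances n of r(e, T_kn + tau); the paired acoustic quantity
averages the auditory spectrogram the same way. Epochs span -100..600 ms
around phoneme onset by default.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats as sps

from .stats import bh_fdr
from .types import (
    AuditorySpectrogram,
    AvgSpectrogramSet,
    EEGRecording,
    EpochSet,
    PhonemeAlignment,
    PRPSet,
    RejectionMask,
)

__all__ = [
    "DEFAULT_WINDOW_MS",
    "extract_epochs",
    "extract_spectrogram_epochs",
    "compute_prp",
    "compute_avg_spectrograms",
    "filter_rare_categories",
    "baseline_significance",
    "grand_average",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_MS = (-100.0, 600.0)


def _epoch_matrix(
    values: np.ndarray,
    fs: float,
    alignment: PhonemeAlignment,
    window_ms: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, list[bool]]:
    lo = int(round(window_ms[0] / 1000.0 * fs))
    hi = int(round(window_ms[1] / 1000.0 * fs))
    lags_ms = np.arange(lo, hi + 1) / fs * 1000.0
    n_samples = values.shape[1]
    epochs = []
    kept = []
    for tok in alignment:
        # onset maps to the nearest sample at or after T (half-open intervals)
        i = int(np.ceil(tok.onset * fs - 1e-9))
        if i + lo < 0 or i + hi >= n_samples:
            kept.append(False)
            continue
        epochs.append(values[:, i + lo : i + hi + 1])
        kept.append(True)
    dropped = len(kept) - sum(kept)
    if dropped:
        logger.info("dropped %d tokens with windows outside the recording", dropped)
    arr = (
        np.stack(epochs)
        if epochs
        else np.zeros((0, values.shape[0], lags_ms.size))
    )
    return arr, lags_ms, kept


def extract_epochs(
    rec: EEGRecording,
    alignment: PhonemeAlignment,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> EpochSet:
    """Segment the EEG around each token onset.

    Tokens whose window falls outside the recording are dropped (logged).
    An empty alignment yields an empty EpochSet with a warning.
    """
    if len(alignment) == 0:
        warnings.warn("empty alignment: returning empty EpochSet", stacklevel=2)
    arr, lags_ms, kept = _epoch_matrix(rec.values, rec.fs, alignment, window_ms)
    sub = alignment.subset(kept)
    return EpochSet(
        arr,
        lags_ms,
        sub.labels,
        sub.speakers,
        [t.utterance for t in sub],
        sub.onsets,
    )


def extract_spectrogram_epochs(
    spec: AuditorySpectrogram,
    alignment: PhonemeAlignment,
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS,
) -> EpochSet:
    """Same segmentation applied to the auditory spectrogram (frequency
    channels take the place of electrodes)."""
    if len(alignment) == 0:
        warnings.warn("empty alignment: returning empty EpochSet", stacklevel=2)
    arr, lags_ms, kept = _epoch_matrix(spec.values, spec.frame_rate, alignment, window_ms)
    sub = alignment.subset(kept)
    return EpochSet(
        arr,
        lags_ms,
        sub.labels,
        sub.speakers,
        [t.utterance for t in sub],
        sub.onsets,
    )


def _category_average(
    epochs: EpochSet, mask: RejectionMask | None, cls: type, subject: str
):
    if mask is None:
        mask = RejectionMask(np.ones(len(epochs), dtype=bool), np.inf)
    if mask.keep.size != len(epochs):
        raise ValueError("rejection mask length must equal epoch count")
    kept = epochs.subset(mask.keep)
    categories = sorted(set(kept.labels))
    values, counts = [], []
    for cat in categories:
        sel = np.array([l == cat for l in kept.labels])
        values.append(kept.epochs[sel].mean(axis=0))
        counts.append(int(sel.sum()))
    if not categories:
        raise ValueError("no epochs left after rejection")
    return cls(np.stack(values), categories, np.array(counts), kept.lags_ms, subject)


def compute_prp(
    epochs: EpochSet, mask: RejectionMask | None = None, subject: str = ""
) -> PRPSet:
    """Average kept epochs within each phoneme category.

    Categories with zero kept tokens are simply absent from the result
    (their exclusion is visible through the ``categories`` list).
    """
    return _category_average(epochs, mask, PRPSet, subject)


def compute_avg_spectrograms(
    epochs: EpochSet, mask: RejectionMask | None = None, subject: str = ""
) -> AvgSpectrogramSet:
    """Category-averaged auditory spectrogram segments, same conventions as
    :func:`compute_prp` so the two spaces stay index-aligned."""
    return _category_average(epochs, mask, AvgSpectrogramSet, subject)


def filter_rare_categories(prp: PRPSet, floor: float = 0.0001) -> PRPSet:
    """Drop categories holding fewer than ``floor`` (fraction) of all phones.

    Default 0.01%: at that floor a category is kept iff
    N_k / sum(N) >= floor.
    """
    if floor < 0:
        raise ValueError("floor must be non-negative")
    total = prp.counts.sum()
    keep = prp.counts / total >= floor
    if not np.any(keep):
        raise ValueError("rare-category filter would drop every category")
    dropped = [c for c, k in zip(prp.categories, keep) if not k]
    if dropped:
        logger.info("rare-category filter dropped %s", dropped)
    return type(prp)(
        prp.values[keep],
        [c for c, k in zip(prp.categories, keep) if k],
        prp.counts[keep],
        prp.lags_ms,
        prp.subject,
    )


def grand_average(prps: list[PRPSet]) -> PRPSet:
    """Unweighted mean over subjects, restricted to shared categories."""
    if not prps:
        raise ValueError("need at least one subject")
    shared = sorted(set.intersection(*(set(p.categories) for p in prps)))
    if not shared:
        raise ValueError("no categories shared across subjects")
    stack = np.stack(
        [np.stack([p.values[p.category_index(c)] for c in shared]) for p in prps]
    )
    counts = np.sum(
        [[p.counts[p.category_index(c)] for c in shared] for p in prps], axis=0
    )
    return PRPSet(stack.mean(axis=0), shared, counts, prps[0].lags_ms, "grand")


def baseline_significance(
    prps: list[PRPSet],
    electrode: int = 0,
    q: float = 0.01,
    baseline_ms: tuple[float, float] = (-100.0, 0.0),
    average_electrodes: bool = False,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Per-lag paired t-test of subject PRPs against each subject's pre-onset
    baseline mean, BH-FDR corrected at ``q``.

    Each subject contributes its all-category mean PRP at ``electrode`` (or
    averaged over electrodes). Returns the boolean per-lag mask and the
    contiguous significant windows in ms.
    """
    if len(prps) < 2:
        raise ValueError("baseline significance needs at least 2 subjects")
    lags = prps[0].lags_ms
    traces = []
    for p in prps:
        v = p.values.mean(axis=0)  # mean over categories -> electrode x lag
        traces.append(v.mean(axis=0) if average_electrodes else v[electrode])
    traces = np.stack(traces)  # subject x lag
    base_sel = (lags >= baseline_ms[0]) & (lags <= baseline_ms[1])
    baseline = traces[:, base_sel].mean(axis=1, keepdims=True)
    diffs = traces - baseline
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diffs.mean(axis=0) / (sd / np.sqrt(traces.shape[0]))
    p_vals = 2 * sps.t.sf(np.abs(t), df=traces.shape[0] - 1)
    p_vals = np.where(np.isnan(p_vals), 1.0, p_vals)
    mask = bh_fdr(p_vals, q)
    windows = []
    in_run = False
    for i, sig in enumerate(mask):
        if sig and not in_run:
            start = lags[i]
            in_run = True
        elif not sig and in_run:
            windows.append((float(start), float(lags[i - 1])))
            in_run = False
    if in_run:
        windows.append((float(start), float(lags[-1])))
    return mask, windows
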