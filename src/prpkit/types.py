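"""Core containers shared across the pipeline.

Conventions
-----------
* Times are seconds (float) on every external surface; sample indices are an
  internal detail. Token intervals are half-open ``[onset, offset)``.
* EEG arrays are ``electrode x time``; spectrograms are ``frequency x time``;
  epoch tensors are ``token x feature x lag``.
* Lag axes are in milliseconds relative to phoneme onset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PhoneToken",
    "PhonemeAlignment",
    "EEGRecording",
    "AuditorySpectrogram",
    "EpochSet",
    "RejectionMask",
    "PRPSet",
    "AvgSpectrogramSet",
    "DistanceSeries",
    "SimilarityMatrix",
    "CrossSimilarityMatrix",
    "SpeakerDistanceMatrix",
]


@dataclass(frozen=True)
class PhoneToken:
    """One phone instance: half-open interval [onset, offset) in seconds."""

    label: str
    onset: float
    offset: float
    speaker: str
    utterance: int

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ValueError(
                f"token {self.label!r}: offset ({self.offset}) must exceed onset ({self.onset})"
            )

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class PhonemeAlignment:
    """Time-ordered phone tokens with speaker and utterance labels."""

    tokens: list[PhoneToken]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.tokens, self.tokens[1:]):
            if cur.onset < prev.onset - 1e-12:
                raise ValueError("alignment tokens must be sorted by onset")
            if cur.utterance == prev.utterance and cur.onset < prev.offset - 1e-9:
                raise ValueError(
                    f"overlapping tokens within utterance {cur.utterance}: "
                    f"{prev.label!r}@{prev.onset:.4f} and {cur.label!r}@{cur.onset:.4f}"
                )

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.tokens]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.tokens], dtype=float)

    @property
    def speakers(self) -> list[str]:
        return [t.speaker for t in self.tokens]

    def subset(self, keep: Sequence[bool]) -> "PhonemeAlignment":
        return PhonemeAlignment([t for t, k in zip(self.tokens, keep) if k])

    def for_speaker(self, speaker_id: str) -> "PhonemeAlignment":
        return PhonemeAlignment([t for t in self.tokens if t.speaker == speaker_id])


@dataclass
class EEGRecording:
    """Multichannel EEG: ``values[e, t]`` at sampling rate ``fs``."""

    values: np.ndarray
    fs: float
    electrode_labels: list[str]
    reference: str = "linked earlobes"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("EEG values must be electrode x time")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.electrode_labels) != self.values.shape[0]:
            raise ValueError("electrode label count must equal row count")

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, values: np.ndarray) -> "EEGRecording":
        return EEGRecording(values, self.fs, list(self.electrode_labels), self.reference)


@dataclass
class AuditorySpectrogram:
    """Peripheral-model output s(f, t): non-negative frequency x time envelope."""

    values: np.ndarray
    center_frequencies: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.center_frequencies = np.asarray(self.center_frequencies, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("spectrogram must be frequency x time")
        if self.values.shape[0] != self.center_frequencies.size:
            raise ValueError("one center frequency per channel required")
        if np.any(self.values < -1e-12):
            raise ValueError("auditory spectrogram must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class EpochSet:
    """Token-aligned segments: ``epochs[n, feature, lag]`` plus per-token metadata.

    ``feature`` is electrodes for neural epochs and frequency channels for
    acoustic epochs; both spaces share this container so the representational
    code paths are identical.
    """

    epochs: np.ndarray
    lags_ms: np.ndarray
    labels: list[str]
    speakers: list[str]
    utterances: list[int]
    onsets: np.ndarray

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        n = self.epochs.shape[0]
        if not (len(self.labels) == len(self.speakers) == len(self.utterances) == n):
            raise ValueError("metadata length must equal epoch count")
        if self.epochs.shape[2] != self.lags_ms.size:
            raise ValueError("lag axis mismatch")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    def subset(self, keep: Sequence[bool] | np.ndarray) -> "EpochSet":
        keep = np.asarray(keep, dtype=bool)
        return EpochSet(
            self.epochs[keep],
            self.lags_ms,
            [l for l, k in zip(self.labels, keep) if k],
            [s for s, k in zip(self.speakers, keep) if k],
            [u for u, k in zip(self.utterances, keep) if k],
            np.asarray(self.onsets)[keep],
        )


@dataclass
class RejectionMask:
    """Per-epoch keep/drop decision from amplitude screening."""

    keep: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def fraction_rejected(self) -> float:
        if self.keep.size == 0:
            return 0.0
        return float(np.count_nonzero(~self.keep)) / self.keep.size


@dataclass
class PRPSet:
    """Phoneme-related potentials: ``values[k, e, lag]`` with counts N_k."""

    values: np.ndarray
    categories: list[str]
    counts: np.ndarray
    lags_ms: np.ndarray
    subject: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        if self.values.shape[0] != len(self.categories):
            raise ValueError("one category label per PRP row required")
        if self.counts.size != len(self.categories):
            raise ValueError("one count per category required")

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def category_index(self, label: str) -> int:
        return self.categories.index(label)

    def lag_index(self, lag_ms: float) -> int:
        return int(np.argmin(np.abs(self.lags_ms - lag_ms)))

    def window_slice(self, start_ms: float, stop_ms: float) -> np.ndarray:
        sel = (self.lags_ms >= start_ms) & (self.lags_ms <= stop_ms)
        return self.values[:, :, sel]


# The average-spectrogram container is structurally identical to a PRPSet
# (categories x feature x lag); a subclass keeps the space tag explicit.
class AvgSpectrogramSet(PRPSet):
    """Category-averaged auditory spectrograms S̄(k, f, τ)."""


@dataclass
class DistanceSeries:
    """Per-lag symmetric category x category Euclidean distance matrices."""

    values: np.ndarray  # lag x K x K
    lags_ms: np.ndarray
    categories: list[str]
    space: str = "neural"  # "neural" (across electrodes) | "acoustic" (across frequencies)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError("distance series must be lag x K x K")
        k = self.values.shape[1]
        if len(self.categories) != k:
            raise ValueError("category label count mismatch")
        if not np.allclose(self.values, np.swapaxes(self.values, 1, 2), atol=1e-9):
            raise ValueError("distance matrices must be symmetric")
        if not np.allclose(np.diagonal(self.values, axis1=1, axis2=2), 0.0, atol=1e-9):
            raise ValueError("distance matrices must have zero diagonal")
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")

    @property
    def n_lags(self) -> int:
        return self.values.shape[0]

    def at(self, lag_ms: float) -> np.ndarray:
        return self.values[int(np.argmin(np.abs(self.lags_ms - lag_ms)))]


@dataclass
class SimilarityMatrix:
    """Similarity m - D, where m is the mean of the distance matrix entries."""

    values: np.ndarray
    categories: list[str]
    lag_ms: float
    m: float


@dataclass
class CrossSimilarityMatrix:
    """Lag x lag covariance between two distance series, with significance mask."""

    values: np.ndarray  # lags_a x lags_b
    lags_a_ms: np.ndarray
    lags_b_ms: np.ndarray
    space_a: str
    space_b: str
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("significance mask must match covariance shape")


@dataclass
class SpeakerDistanceMatrix:
    """(2K) x (2K) distances over speaker-phoneme items.

    Row/column order is all K categories of speaker 1 followed by the same K
    categories of speaker 2, so the diagonal quadrants hold within-speaker
    distances and the off-diagonal quadrants hold between-speaker distances.
    """

    values: np.ndarray
    categories: list[str]
    speakers: tuple[str, str]
    lag_ms: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k2 = 2 * len(self.categories)
        if self.values.shape != (k2, k2):
            raise ValueError("speaker distance matrix must be 2K x 2K")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("speaker distance matrix must be symmetric")

    @property
    def k(self) -> int:
        return len(self.categories)

    @property
    def within_1(self) -> np.ndarray:
        return self.values[: self.k, : self.k]

    @property
    def within_2(self) -> np.ndarray:
        return self.values[self.k :, self.k :]

    @property
    def between_12(self) -> np.ndarray:
        """d_BS1(i, j) = distance(speaker-1 phoneme i, speaker-2 phoneme j)."""
        return self.values[: self.k, self.k :]

    @property
    def between_21(self) -> np.ndarray:
        return self.values[self.k :, : self.k]
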