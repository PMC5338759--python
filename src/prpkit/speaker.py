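"""Speaker-resolved representational analysis.

Computing PRPs (or average spectrograms) separately per speaker yields, at
each lag, a (2K) x (2K) distance matrix over speaker-phoneme items whose
diagonal quadrants are within-speaker and off-diagonal quadrants are
between-speaker distances. From it follow the scalar speaker index, the
per-phoneme speaker-dependent encoding index SE(i), and the lag x lag
correlation map between speaker-dependent patterns in neural and acoustic
space. Neural and acoustic inputs run through identical code.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform
from scipy import stats as sps

from .stats import bh_fdr
from .types import DistanceSeries, PRPSet, SpeakerDistanceMatrix

__all__ = [
    "speaker_distance_matrix",
    "speaker_distance_series",
    "speaker_index",
    "speaker_pattern",
    "speaker_neural_acoustic_map",
    "se_index",
    "se_correlation",
]


def _check_pair(prp_a: PRPSet, prp_b: PRPSet) -> None:
    if prp_a.categories != prp_b.categories:
        raise ValueError("both speakers must cover the same categories in the same order")


def speaker_distance_matrix(
    prp_a: PRPSet,
    prp_b: PRPSet,
    lag_ms: float,
    speakers: tuple[str, str] = ("S1", "S2"),
) -> SpeakerDistanceMatrix:
    """Euclidean distances among all 2K speaker-phoneme items at one lag."""
    _check_pair(prp_a, prp_b)
    t = prp_a.lag_index(lag_ms)
    stacked = np.vstack([prp_a.values[:, :, t], prp_b.values[:, :, t]])
    return SpeakerDistanceMatrix(
        squareform(pdist(stacked)), list(prp_a.categories), speakers, lag_ms
    )


def speaker_distance_series(
    prp_a: PRPSet, prp_b: PRPSet, speakers: tuple[str, str] = ("S1", "S2")
) -> list[SpeakerDistanceMatrix]:
    return [
        speaker_distance_matrix(prp_a, prp_b, lag, speakers) for lag in prp_a.lags_ms
    ]


def speaker_index(m: SpeakerDistanceMatrix) -> float:
    """mean(within-speaker distances) - mean(between-speaker distances).

    Self pairs (i = j) are excluded from every quadrant: they are structural
    zeros within speaker and the same-phoneme cross-speaker distances between
    speakers, so with identical speakers the index is exactly 0. Negative
    values mean the two speakers' phoneme sets are farther apart than
    phonemes are from each other within a speaker.
    """
    k = m.k
    off = ~np.eye(k, dtype=bool)
    within = np.concatenate([m.within_1[off], m.within_2[off]])
    between = np.concatenate([m.between_12[off], m.between_21[off]])
    return float(within.mean() - between.mean())


def _pattern_from_blocks(w1: np.ndarray, w2: np.ndarray, b12: np.ndarray) -> np.ndarray:
    """Speaker-dependent pattern vector at one lag.

    One entry per unordered pair i < j: the between-minus-within contrast
    [b12(i,j) + b12(j,i)] / 2 - [w1(i,j) + w2(i,j)] / 2. Subtracting the
    within-speaker structure isolates what the speaker difference adds; the
    same-phoneme diagonal b12(i,i) is deliberately excluded -- with finite
    per-category counts it is dominated by estimation noise whose size
    tracks category counts in *both* spaces, which would correlate the two
    maps at every lag pair.
    """
    rows, cols = np.triu_indices(w1.shape[0], k=1)
    return (b12[rows, cols] + b12[cols, rows]) / 2 - (
        w1[rows, cols] + w2[rows, cols]
    ) / 2


def speaker_pattern(prp_a: PRPSet, prp_b: PRPSet, lag_ms: float) -> np.ndarray:
    """Vectorized speaker-dependent distance pattern at one lag."""
    _check_pair(prp_a, prp_b)
    t = prp_a.lag_index(lag_ms)
    xa = prp_a.values[:, :, t]
    xb = prp_b.values[:, :, t]
    w1 = squareform(pdist(xa))
    w2 = squareform(pdist(xb))
    b12 = cdist(xa, xb)
    return _pattern_from_blocks(w1, w2, b12)


def speaker_neural_acoustic_map(
    neural: tuple[PRPSet, PRPSet],
    acoustic: tuple[PRPSet, PRPSet],
    q: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Lag x lag Pearson correlation between speaker-dependent patterns in
    neural and acoustic space, BH-FDR masked at ``q``.

    Returns (r map, significance mask, neural lags, acoustic lags). Cells
    where either pattern is constant are undefined (r = nan, never
    significant).
    """
    na, nb = neural
    aa, ab = acoustic
    _check_pair(na, nb)
    _check_pair(aa, ab)
    if na.categories != aa.categories:
        raise ValueError("neural and acoustic spaces must share categories")
    pat_n = np.stack([speaker_pattern(na, nb, lag) for lag in na.lags_ms])
    pat_a = np.stack([speaker_pattern(aa, ab, lag) for lag in aa.lags_ms])
    n_pairs = pat_n.shape[1]
    nc = pat_n - pat_n.mean(axis=1, keepdims=True)
    ac = pat_a - pat_a.mean(axis=1, keepdims=True)
    nn = np.sqrt((nc**2).sum(axis=1))
    an = np.sqrt((ac**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (nc @ ac.T) / np.outer(nn, an)
    valid = np.isfinite(r)
    df = n_pairs - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1 - r**2, 1e-300))
    p = np.where(valid, 2 * sps.t.sf(np.abs(t), df), 1.0)
    p = np.clip(p, 0.0, 1.0)
    mask = bh_fdr(p, q)
    mask &= valid
    return r, mask, na.lags_ms, aa.lags_ms


def se_index(
    prp_a: PRPSet,
    prp_b: PRPSet,
    window_ms: tuple[float, float] = (0.0, 400.0),
) -> np.ndarray:
    """Speaker-dependent encoding SE(i) per phoneme category.

    Distances are Euclidean between concatenated feature x lag vectors inside
    ``window_ms``. For each category i,

        SE(i) = mean over j != i of
                [ (d_BS1(i,j) + d_BS2(i,j)) - (d_WS1(i,j) + d_WS2(i,j)) ] / 2

    i.e. between-speaker minus within-speaker distances, so SE(i) = 0 when
    the two speakers' representations are identical and SE grows as their
    representations separate. SE may be negative; no non-negativity is
    assumed.
    """
    _check_pair(prp_a, prp_b)
    k = prp_a.n_categories
    if k < 2:
        raise ValueError("SE needs at least 2 categories")
    xa = prp_a.window_slice(*window_ms).reshape(k, -1)
    xb = prp_b.window_slice(*window_ms).reshape(k, -1)
    w1 = squareform(pdist(xa))  # d_WS1
    w2 = squareform(pdist(xb))  # d_WS2
    b12 = cdist(xa, xb)  # d_BS1(i, j); d_BS2(i, j) = b12.T[i, j]
    off = ~np.eye(k, dtype=bool)
    se = np.empty(k)
    for i in range(k):
        j = off[i]
        se[i] = np.mean((b12[i, j] + b12.T[i, j]) - (w1[i, j] + w2[i, j])) / 2
    return se


def se_correlation(se_neural: np.ndarray, se_acoustic: np.ndarray) -> tuple[float, float]:
    """Pearson r (with t-based p) between neural and acoustic SE vectors."""
    a = np.asarray(se_neural, dtype=float)
    b = np.asarray(se_acoustic, dtype=float)
    if a.shape != b.shape:
        raise ValueError("SE vectors must share category ordering and length")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("SE correlation undefined for constant vectors")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)
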