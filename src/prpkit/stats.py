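"""Group-level statistics: manner-of-articulation F time courses, BH-FDR,
effect-size accumulation, and the regularized least-squares manner classifier.

The F statistic at each lag is a one-way ANOVA across manner groups; the same
code path serves neural ("response") and acoustic ("stimulus") inputs, which
is what licenses their direct comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.linear_model import Ridge
from sklearn.model_selection import train_test_split
from statsmodels.stats.multitest import multipletests

from .types import EpochSet, PRPSet

__all__ = [
    "MannerPartition",
    "FSeries",
    "ConfusionMatrix",
    "bh_fdr",
    "f_oneway_lags",
    "manner_f_series",
    "units_from_prps",
    "units_from_epochs",
    "per_electrode_f_maps",
    "effect_size_accumulation",
    "rls_classifier",
    "predict_rls",
    "confusion_correlation",
    "DEFAULT_COMPONENT_WINDOWS_MS",
]

MANNERS = ("plosive", "fricative", "nasal", "vowel")

# analysis windows around the four PRP components (R1-R4)
DEFAULT_COMPONENT_WINDOWS_MS = {
    "R1": (30.0, 70.0),
    "R2": (100.0, 140.0),
    "R3": (210.0, 250.0),
    "R4": (380.0, 420.0),
}


@dataclass(frozen=True)
class MannerPartition:
    """Total mapping phoneme -> manner group."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {m for m in self.mapping.values()} - set(MANNERS)
        if bad:
            raise ValueError(f"unknown manner groups: {sorted(bad)}")

    def group(self, label: str) -> str:
        return self.mapping[label]

    def groups_for(self, labels: list[str]) -> np.ndarray:
        return np.array([self.mapping[l] for l in labels])


@dataclass
class FSeries:
    """Per-lag F statistic with its FDR significance mask."""

    f: np.ndarray
    p: np.ndarray
    df_between: int
    df_within: int
    mask: np.ndarray
    lags_ms: np.ndarray
    source: str = "response"  # "response" (neural) | "stimulus" (acoustic)
    exact_separation: np.ndarray | None = None

    def peak_lag(self, window_ms: tuple[float, float] | None = None) -> float:
        sel = (
            np.ones_like(self.lags_ms, dtype=bool)
            if window_ms is None
            else (self.lags_ms >= window_ms[0]) & (self.lags_ms <= window_ms[1])
        )
        idx = np.flatnonzero(sel)
        return float(self.lags_ms[idx[np.argmax(self.f[idx])]])


def bh_fdr(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up at level ``q`` -> boolean rejection mask."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


def f_oneway_lags(
    values: np.ndarray, groups: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int, int, np.ndarray]:
    """Vectorized one-way ANOVA across lags.

    ``values`` is unit x lag; ``groups`` assigns each unit to a group. Returns
    (F, p, df_between, df_within, exact_separation). Cells with zero
    within-group variance but non-zero between-group variance yield +inf F
    (flagged), p = 0.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least 2 groups")
    n = values.shape[0]
    grand = values.mean(axis=0)
    ss_between = np.zeros(values.shape[1])
    ss_within = np.zeros(values.shape[1])
    for g in uniq:
        sel = groups == g
        ng = int(sel.sum())
        if ng < 2:
            raise ValueError(f"group {g!r} has fewer than 2 units")
        gm = values[sel].mean(axis=0)
        ss_between += ng * (gm - grand) ** 2
        ss_within += ((values[sel] - gm) ** 2).sum(axis=0)
    df_b = uniq.size - 1
    df_w = n - uniq.size
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    exact = (ss_within == 0) & (ss_between > 0)
    f = np.where(exact, np.inf, f)
    f = np.where((ss_within == 0) & (ss_between == 0), 0.0, f)
    p = sps.f.sf(f, df_b, df_w)
    p = np.where(np.isnan(p), 1.0, p)
    return f, p, df_b, df_w, exact


def units_from_prps(
    prps: list[PRPSet], partition: MannerPartition, electrode: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Category x subject analysis units at one electrode.

    Each retained (category, subject) pair contributes its PRP trace; groups
    are the categories' manners. This is the grand-average framing; token-level
    units come from :func:`units_from_epochs`.
    """
    rows, groups = [], []
    for p in prps:
        for k, cat in enumerate(p.categories):
            rows.append(p.values[k, electrode])
            groups.append(partition.group(cat))
    return np.stack(rows), np.array(groups), prps[0].lags_ms


def units_from_epochs(
    epochs: EpochSet, partition: MannerPartition, electrode: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Token-level analysis units at one electrode."""
    return (
        epochs.epochs[:, electrode, :],
        partition.groups_for(epochs.labels),
        epochs.lags_ms,
    )


def manner_f_series(
    values: np.ndarray,
    groups: np.ndarray,
    lags_ms: np.ndarray,
    q: float = 0.05,
    source: str = "response",
) -> FSeries:
    """F-statistic time course for manner separability with BH-FDR mask."""
    f, p, df_b, df_w, exact = f_oneway_lags(values, groups)
    mask = bh_fdr(p, q)
    return FSeries(f, p, df_b, df_w, mask, np.asarray(lags_ms, dtype=float), source, exact)


def per_electrode_f_maps(
    epochs: EpochSet,
    partition: MannerPartition,
    windows_ms: dict[str, tuple[float, float]] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Per-electrode F statistic averaged within each component window.

    Returns an electrode x window matrix and the window names; the scalp-map
    values behind topography plots.
    """
    windows_ms = windows_ms or DEFAULT_COMPONENT_WINDOWS_MS
    names = list(windows_ms)
    groups = partition.groups_for(epochs.labels)
    n_e = epochs.epochs.shape[1]
    out = np.zeros((n_e, len(names)))
    for e in range(n_e):
        f, *_ = f_oneway_lags(epochs.epochs[:, e, :], groups)
        for w, name in enumerate(names):
            lo, hi = windows_ms[name]
            sel = (epochs.lags_ms >= lo) & (epochs.lags_ms <= hi)
            if not np.any(sel):
                raise ValueError(f"window {name} outside the lag range")
            out[e, w] = np.mean(f[sel])
    return out, names


def effect_size_accumulation(
    subject_epochs: list[EpochSet],
    partition: MannerPartition,
    electrode: int,
    n_subjects_grid: list[int],
    duration_grid_s: list[float],
    n_repeats: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Peak F at one electrode as subjects and recording time accumulate.

    For each (n_subjects, duration) cell, subsample that many subjects and
    keep only tokens with onsets inside the initial ``duration`` seconds,
    pool token-level units, and take the maximum F across lags; the cell
    value is the mean over ``n_repeats`` seeded subject draws. Grid entries
    exceeding the available data are truncated with a warning.
    """
    import warnings

    if len(subject_epochs) < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    n_avail = len(subject_epochs)
    out = np.full((len(n_subjects_grid), len(duration_grid_s)), np.nan)
    for i, ns in enumerate(n_subjects_grid):
        if ns > n_avail:
            warnings.warn(f"grid requests {ns} subjects, only {n_avail} available", stacklevel=2)
            ns = n_avail
        for j, dur in enumerate(duration_grid_s):
            peaks = []
            for _ in range(n_repeats):
                chosen = rng.choice(n_avail, size=ns, replace=False)
                vals, grps = [], []
                for s in chosen:
                    ep = subject_epochs[s]
                    sel = np.asarray(ep.onsets) < dur
                    if np.any(sel):
                        sub = ep.subset(sel)
                        v, g, _ = units_from_epochs(sub, partition, electrode)
                        vals.append(v)
                        grps.append(g)
                if not vals:
                    continue
                v = np.concatenate(vals)
                g = np.concatenate(grps)
                if np.unique(g).size < 2 or min(np.bincount(np.unique(g, return_inverse=True)[1])) < 2:
                    continue
                f, *_ = f_oneway_lags(v, g)
                peaks.append(np.max(f[np.isfinite(f)]) if np.any(np.isfinite(f)) else np.nan)
            if peaks:
                out[i, j] = float(np.nanmean(peaks))
    return out


@dataclass
class ConfusionMatrix:
    """Held-out confusion counts: rows = true class, columns = predicted."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("confusion matrix must be square over the class list")

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def per_class_accuracy(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.diag(self.counts) / self.counts.sum(axis=1)

    def row_normalized(self) -> np.ndarray:
        sums = self.counts.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return self.counts / sums


@dataclass
class RLSModel:
    """One-vs-rest ridge (regularized least squares) on flattened epochs."""

    models: list[Ridge]
    classes: list[str]
    alpha: float
    mean: np.ndarray
    scale: np.ndarray


def _flatten(epochs: EpochSet) -> np.ndarray:
    return epochs.epochs.reshape(len(epochs), -1)


def predict_rls(model: RLSModel, x: np.ndarray) -> np.ndarray:
    xs = (x - model.mean) / model.scale
    scores = np.column_stack([m.predict(xs) for m in model.models])
    return np.asarray(model.classes)[np.argmax(scores, axis=1)]


def rls_classifier(
    epochs: EpochSet,
    labels: np.ndarray | list[str],
    holdout: float = 0.10,
    seed: int = 0,
    alphas: np.ndarray | None = None,
) -> tuple[RLSModel, ConfusionMatrix]:
    """Train a one-vs-rest ridge classifier on flattened electrode x lag
    vectors; the held-out fraction (default 10%) yields the confusion matrix.

    Regularization is chosen on an inner 90/10 split of the training part,
    over a logarithmic grid 1e-3..1e3.
    """
    y = np.asarray(labels)
    x = _flatten(epochs)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    alphas = np.logspace(-3, 3, 7) if alphas is None else np.asarray(alphas)
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=holdout, random_state=seed, stratify=y
    )
    if set(y_tr) != set(classes) or set(y_te) != set(classes):
        raise ValueError("every class must appear in both train and test splits")
    x_in, x_val, y_in, y_val = train_test_split(
        x_tr, y_tr, test_size=0.10, random_state=seed, stratify=y_tr
    )
    mean = x_in.mean(axis=0)
    scale = x_in.std(axis=0)
    scale[scale == 0] = 1.0

    def fit(alpha: float, xs: np.ndarray, ys: np.ndarray) -> list[Ridge]:
        out = []
        for c in classes:
            m = Ridge(alpha=alpha)
            m.fit(xs, (ys == c).astype(float) * 2 - 1)
            out.append(m)
        return out

    best_alpha, best_acc = alphas[0], -1.0
    xs_in = (x_in - mean) / scale
    xs_val = (x_val - mean) / scale
    for a in alphas:
        ms = fit(a, xs_in, y_in)
        scores = np.column_stack([m.predict(xs_val) for m in ms])
        pred = np.asarray(classes)[np.argmax(scores, axis=1)]
        acc = float(np.mean(pred == y_val))
        if acc > best_acc:
            best_alpha, best_acc = float(a), acc

    mean = x_tr.mean(axis=0)
    scale = x_tr.std(axis=0)
    scale[scale == 0] = 1.0
    final = fit(best_alpha, (x_tr - mean) / scale, y_tr)
    model = RLSModel(final, classes, best_alpha, mean, scale)
    pred = predict_rls(model, x_te)
    counts = np.zeros((len(classes), len(classes)))
    for yt, yp in zip(y_te, pred):
        counts[classes.index(yt), classes.index(yp)] += 1
    return model, ConfusionMatrix(counts, classes)


def confusion_correlation(
    neural: ConfusionMatrix,
    acoustic: ConfusionMatrix,
    off_diagonal_only: bool = False,
) -> tuple[float, float]:
    """Pearson correlation between row-normalized confusion patterns.

    By default all cells are compared; ``off_diagonal_only`` restricts to
    confusions proper. p-value from the t-distribution transform of r.
    """
    if neural.classes != acoustic.classes:
        raise ValueError("confusion matrices must share class ordering")
    a = neural.row_normalized()
    b = acoustic.row_normalized()
    if off_diagonal_only:
        m = ~np.eye(len(neural.classes), dtype=bool)
        a, b = a[m], b[m]
    else:
        a, b = a.ravel(), b.ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("confusion correlation undefined for constant matrices")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)
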