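"""Time-resolved representational analysis.

At every lag relative to phoneme onset, the category x category Euclidean
distance matrix summarizes how phonemes are organized in a space (electrodes
for neural data, frequency channels for acoustic data). Comparing those
matrices across lags and across spaces -- via lower-triangle covariance,
hierarchical clustering, multidimensional scaling and silhouette indices --
exposes when the acoustic organization of phonemes re-appears in the EEG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy import stats as sps

from .stats import bh_fdr
from .types import (
    CrossSimilarityMatrix,
    DistanceSeries,
    EpochSet,
    PRPSet,
    SimilarityMatrix,
)

__all__ = [
    "pairwise_distance_series",
    "similarity",
    "cross_covariance",
    "bootstrap_significance",
    "UpgmaNode",
    "upgma_cluster",
    "to_newick",
    "mds_embed",
    "mds_series",
    "silhouette_index",
]


def pairwise_distance_series(featureset: PRPSet) -> DistanceSeries:
    """Euclidean distance between category vectors (across the feature axis)
    at every lag."""
    if featureset.n_categories < 2:
        raise ValueError("need at least 2 categories for pairwise distances")
    k = featureset.n_categories
    n_lags = featureset.lags_ms.size
    out = np.zeros((n_lags, k, k))
    for t in range(n_lags):
        out[t] = squareform(pdist(featureset.values[:, :, t]))
    space = "acoustic" if type(featureset).__name__ == "AvgSpectrogramSet" else "neural"
    return DistanceSeries(out, featureset.lags_ms, list(featureset.categories), space)


def similarity(
    d: np.ndarray, categories: list[str], lag_ms: float = 0.0, triangle_only: bool = False
) -> SimilarityMatrix:
    """Similarity m - D with m the mean of D's entries.

    ``m`` averages all entries including the zero diagonal by default;
    ``triangle_only`` averages the strict lower triangle instead.
    """
    d = np.asarray(d, dtype=float)
    if triangle_only:
        m = float(np.mean(d[np.tril_indices(d.shape[0], k=-1)]))
    else:
        m = float(d.mean())
    return SimilarityMatrix(m - d, categories, lag_ms, m)


def _lower_triangles(series: DistanceSeries) -> np.ndarray:
    """lag x n_pairs matrix of strict-lower-triangle vectors."""
    k = series.values.shape[1]
    rows, cols = np.tril_indices(k, k=-1)
    return series.values[:, rows, cols]


def cross_covariance(
    series_a: DistanceSeries, series_b: DistanceSeries
) -> CrossSimilarityMatrix:
    """Lag x lag covariance between vectorized strict lower triangles.

    Only the lower triangle enters, to avoid the double-counting bias of the
    symmetric matrix. cov uses the unbiased (n-1) normalizer.
    """
    if series_a.categories != series_b.categories:
        raise ValueError("distance series must share category set and order")
    a = _lower_triangles(series_a)
    b = _lower_triangles(series_b)
    n_pairs = a.shape[1]
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    vals = ac @ bc.T / (n_pairs - 1)
    return CrossSimilarityMatrix(
        vals, series_a.lags_ms, series_b.lags_ms, series_a.space, series_b.space
    )


def _category_means(epochs: EpochSet, categories: list[str], idx: np.ndarray) -> np.ndarray:
    cat_of = np.array([categories.index(l) for l in epochs.labels])
    sel = epochs.epochs[idx]
    cats = cat_of[idx]
    out = np.zeros((len(categories),) + epochs.epochs.shape[1:])
    counts = np.bincount(cats, minlength=len(categories)).astype(float)
    np.add.at(out, cats, sel)
    counts[counts == 0] = np.nan
    return out / counts[:, None, None]


def _distance_series_from_means(means: np.ndarray, lags: np.ndarray, space: str) -> DistanceSeries:
    n_lags = means.shape[2]
    k = means.shape[0]
    out = np.zeros((n_lags, k, k))
    for t in range(n_lags):
        out[t] = squareform(pdist(means[:, :, t]))
    return DistanceSeries(out, lags, [str(i) for i in range(k)], space)


def bootstrap_significance(
    epochs_a: EpochSet,
    epochs_b: EpochSet,
    n: int = 20,
    q: float = 0.0001,
    seed: int = 0,
) -> CrossSimilarityMatrix:
    """Paired token bootstrap of the lag x lag covariance with a BH-FDR mask.

    Tokens are resampled with replacement (the same draw applied to both
    spaces, which must describe the same token sequence); the covariance map
    is recomputed for each resample. Per-cell p-values come from a
    bootstrap-t null against zero covariance -- the two-sided t(n-1) tail of
    mean/std of the resampled covariances -- and are BH-FDR corrected at
    ``q``. Metadata records the null definition.
    """
    if n < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    if n < 5:
        warnings.warn(f"bootstrap with n = {n} resamples has very low power", stacklevel=2)
    if epochs_a.labels != epochs_b.labels:
        raise ValueError("bootstrap requires the same token sequence in both spaces")
    categories = sorted(set(epochs_a.labels))
    if len(categories) < 2:
        raise ValueError("need at least 2 categories")
    rng = np.random.default_rng(seed)
    n_tok = len(epochs_a)

    def cov_for(idx: np.ndarray) -> np.ndarray:
        ma = _category_means(epochs_a, categories, idx)
        mb = _category_means(epochs_b, categories, idx)
        if np.any(np.isnan(ma)) or np.any(np.isnan(mb)):
            # resample missed a category; fall back to the full-sample mean there
            full = np.arange(n_tok)
            fa = _category_means(epochs_a, categories, full)
            fb = _category_means(epochs_b, categories, full)
            ma = np.where(np.isnan(ma), fa, ma)
            mb = np.where(np.isnan(mb), fb, mb)
        sa = _distance_series_from_means(ma, epochs_a.lags_ms, "a")
        sb = _distance_series_from_means(mb, epochs_b.lags_ms, "b")
        return cross_covariance(sa, sb).values

    observed = cov_for(np.arange(n_tok))
    boots = np.stack([cov_for(rng.integers(0, n_tok, size=n_tok)) for _ in range(n)])
    mean = boots.mean(axis=0)
    std = boots.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(mean) / std
    p = 2 * sps.t.sf(t, df=n - 1)
    p = np.where(np.isnan(p), 1.0, p)
    mask = bh_fdr(p, q)
    return CrossSimilarityMatrix(
        observed,
        epochs_a.lags_ms,
        epochs_b.lags_ms,
        "neural",
        "acoustic",
        mask=mask,
        meta={
            "n_bootstrap": n,
            "q": q,
            "seed": seed,
            "null": "bootstrap-t: two-sided t(n-1) tail of mean/std of resampled covariances vs 0",
            "p": p,
        },
    )


@dataclass
class UpgmaNode:
    """Binary dendrogram node; ``height`` is half the merge distance
    (ultrametric convention), leaves have height 0."""

    height: float
    label: str | None = None
    left: "UpgmaNode | None" = None
    right: "UpgmaNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.left.leaves() + self.right.leaves()


def upgma_cluster(
    prp: PRPSet | None = None,
    window_ms: tuple[float, float] = (0.0, 400.0),
    distance_matrix: np.ndarray | None = None,
    labels: list[str] | None = None,
) -> UpgmaNode:
    """Average-linkage (UPGMA) tree over phoneme categories.

    By default the distance is Euclidean between each category's concatenated
    electrode x lag vector inside ``window_ms`` (the interval holding the
    significant PRP components). A precomputed ``distance_matrix`` (with
    ``labels``) may be supplied instead. Ties are broken by the lowest
    (row, column) index pair, making the result deterministic and invariant
    to category order whenever distances are distinct.
    """
    if distance_matrix is None:
        if prp is None:
            raise ValueError("provide a PRPSet or a distance matrix")
        if prp.n_categories < 2:
            raise ValueError("need at least 2 categories")
        vecs = prp.window_slice(*window_ms).reshape(prp.n_categories, -1)
        distance_matrix = squareform(pdist(vecs))
        labels = list(prp.categories)
    d = np.asarray(distance_matrix, dtype=float).copy()
    if labels is None or len(labels) != d.shape[0]:
        raise ValueError("labels must match the distance matrix")
    nodes: list[UpgmaNode] = [UpgmaNode(0.0, label=l) for l in labels]
    sizes = [1] * len(labels)
    active = list(range(len(labels)))
    while len(active) > 1:
        best = None
        for ii, a in enumerate(active):
            for b in active[ii + 1 :]:
                key = (d[a, b], a, b)
                if best is None or key < best:
                    best = key
        dist, a, b = best
        merged = UpgmaNode(dist / 2.0, left=nodes[a], right=nodes[b])
        # UPGMA: distance from the new cluster is the size-weighted average
        new_row = np.zeros(d.shape[0] + 1)
        for c in active:
            if c in (a, b):
                continue
            new_row[c] = (sizes[a] * d[a, c] + sizes[b] * d[b, c]) / (sizes[a] + sizes[b])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : new_row.size - 1] = new_row[:-1]
        d[: new_row.size - 1, -1] = new_row[:-1]
        nodes.append(merged)
        sizes.append(sizes[a] + sizes[b])
        active = [c for c in active if c not in (a, b)] + [len(nodes) - 1]
    return nodes[active[0]]


def to_newick(node: UpgmaNode) -> str:
    """Newick serialization with branch lengths from ultrametric heights."""

    def render(n: UpgmaNode, parent_height: float) -> str:
        bl = parent_height - n.height
        if n.is_leaf:
            return f"{n.label}:{bl:.6g}"
        inner = f"({render(n.left, n.height)},{render(n.right, n.height)})"
        return f"{inner}:{bl:.6g}"

    if node.is_leaf:
        return f"{node.label};"
    return f"({render(node.left, node.height)},{render(node.right, node.height)});"


def mds_embed(
    d: np.ndarray,
    dims: int = 1,
    seed: int = 0,
    n_init: int = 8,
    first_nonnegative: bool = True,
) -> tuple[np.ndarray, float]:
    """Non-metric MDS (Kruskal stress-1), centered, with a fixed sign
    convention (first item non-negative in dimension 1).

    Returns (coordinates, stress). ``dims`` must be < number of items. The
    two-item case is embedded exactly at +/- d/2.
    """
    d = np.asarray(d, dtype=float)
    k = d.shape[0]
    if dims < 1 or dims > 3:
        raise ValueError("dims must be 1, 2 or 3")
    if dims > k - 1:
        raise ValueError("dims must be at most n_items - 1")
    if k == 2:
        coords = np.zeros((2, dims))
        coords[0, 0] = -d[0, 1] / 2
        coords[1, 0] = d[0, 1] / 2
        stress = 0.0
    else:
        from sklearn.manifold import MDS

        common = dict(
            n_components=dims,
            n_init=n_init,
            random_state=seed,
            max_iter=3000,
            eps=1e-12,
            normalized_stress=True,
        )
        try:  # sklearn >= 1.9 API
            mds = MDS(metric="precomputed", metric_mds=False, init="random", **common)
        except TypeError:  # older API
            mds = MDS(metric=False, dissimilarity="precomputed", **common)
        coords = mds.fit_transform(d)
        stress = float(mds.stress_)
    coords = coords - coords.mean(axis=0)
    if first_nonnegative and coords[0, 0] < 0:
        coords[:, 0] *= -1
    return coords, stress


def mds_series(
    series: DistanceSeries,
    dims: int = 1,
    zero_mask: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-lag MDS trajectory: ``lag x category x dims``.

    Lags flagged in ``zero_mask`` (e.g. no electrode significant there) emit
    all-zero coordinates.
    """
    n_lags = series.n_lags
    k = series.values.shape[1]
    out = np.zeros((n_lags, k, dims))
    zero_mask = (
        np.zeros(n_lags, dtype=bool) if zero_mask is None else np.asarray(zero_mask, bool)
    )
    for t in range(n_lags):
        if zero_mask[t]:
            continue
        out[t], _ = mds_embed(series.values[t], dims=dims, seed=seed)
    return out


def silhouette_index(
    d: np.ndarray | None,
    labels: np.ndarray | list[str],
    vectors: np.ndarray | None = None,
) -> float:
    """Mean silhouette over items: (b - a) / max(a, b).

    ``a`` is the mean distance to same-label items, ``b`` the smallest mean
    distance to another label's items. Items in singleton clusters score 0.
    Accepts a precomputed distance matrix or raw vectors.
    """
    if d is None:
        if vectors is None:
            raise ValueError("provide a distance matrix or vectors")
        d = squareform(pdist(np.asarray(vectors, dtype=float)))
    d = np.asarray(d, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct labels")
    if np.all(np.bincount(np.searchsorted(uniq, labels)) == 1):
        raise ValueError("silhouette undefined when every cluster is a singleton")
    scores = np.zeros(labels.size)
    for i in range(labels.size):
        same = (labels == labels[i]) & (np.arange(labels.size) != i)
        if not np.any(same):
            scores[i] = 0.0
            continue
        a = d[i, same].mean()
        b = min(d[i, labels == other].mean() for other in uniq if other != labels[i])
        scores[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(scores.mean())
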