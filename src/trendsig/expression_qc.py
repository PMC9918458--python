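"""Normalization and QC for the assembled multi-study expression matrix.

Operations mirror the standard microarray meta-analysis toolkit: quantile
normalization, top-variance probe selection, PCA for cohort homogeneity
checks, complete-linkage hierarchical clustering of samples, sample
exclusion, and per-probe z-scoring for heatmap display.

All functions take/return pandas objects: the matrix is probes x samples
with unique string indices on both axes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .errors import ValidationError

_VALID_METRICS = {"euclidean", "cityblock", "correlation", "cosine"}


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean empirical distribution.

    After the transform each column's sorted values equal the across-sample
    mean of sorted values; rank ties receive the mean of the corresponding
    reference quantiles, which makes the operation idempotent.
    """
    if m.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    if not np.isfinite(m.to_numpy()).all():
        raise ValidationError("non-finite values in expression matrix")
    x = m.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    n = x.shape[0]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")  # 1..n, .5 on ties
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def select_top_variance(m: pd.DataFrame, k: int) -> list[str]:
    """The ``k`` probes of largest sample variance, descending; ties broken
    by probe id."""
    if k > m.shape[0]:
        raise ValidationError(f"k={k} exceeds {m.shape[0]} probes")
    var = m.var(axis=1, ddof=1)
    order = sorted(m.index, key=lambda p: (-var[p], p))
    return order[:k]


def pca(m: pd.DataFrame, n_components: int = 2):
    """Sample-space PCA on the probe matrix.

    Samples (columns) are the observations; they are mean-centred before the
    decomposition. Returns ``(scores, loadings, variance_explained)`` where
    scores is samples x components and loadings is components x probes. Each
    loading vector is oriented so its largest-magnitude entry is positive,
    making the output deterministic.
    """
    if m.shape[1] < 2:
        raise ValidationError("PCA needs >= 2 samples")
    if n_components > min(m.shape):
        raise ValidationError("n_components exceeds matrix rank bound")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(m.to_numpy(dtype=float).T)
    loadings = model.components_
    for i in range(loadings.shape[0]):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    comp_ix = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(scores, index=m.columns, columns=comp_ix),
        pd.DataFrame(loadings, index=comp_ix, columns=m.index),
        pd.Series(model.explained_variance_ratio_, index=comp_ix,
                  name="variance_explained"),
    )


def hierarchical_cluster(m: pd.DataFrame, k: int | None = None,
                         method: str = "complete", metric: str = "euclidean"):
    """Agglomerative clustering of samples (columns).

    Returns the scipy merge tree ``Z`` (n-1 rows) and, when ``k`` is given, a
    Series of flat cluster labels per sample cut at ``k`` clusters.
    """
    if m.shape[1] < 2:
        raise ValidationError("clustering needs >= 2 samples")
    if metric not in _VALID_METRICS:
        raise ValidationError(f"unknown metric {metric!r}")
    Z = linkage(m.to_numpy(dtype=float).T, method=method, metric=metric)
    labels = None
    if k is not None:
        labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"),
                           index=m.columns, name="cluster")
    return Z, labels


def exclude_samples(m: pd.DataFrame, sheet: pd.DataFrame, ids):
    """Drop the given sample ids from matrix and sheet, preserving order."""
    ids = list(ids)
    unknown = [s for s in ids if s not in m.columns]
    if unknown:
        raise ValidationError(f"unknown sample ids: {unknown}")
    keep = [s for s in m.columns if s not in set(ids)]
    return m[keep], sheet[sheet["sample_id"].isin(keep)].reset_index(drop=True)


def zscore_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Per-probe standardization (mean 0, sd 1; sample sd, ddof=1)."""
    sd = m.std(axis=1, ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise ValidationError(f"constant rows cannot be z-scored: "
                              f"{list(flat.index[:5])}")
    return m.sub(m.mean(axis=1), axis=0).div(sd, axis=0)
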