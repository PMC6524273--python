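"""Sample-level structure: PCA and silhouette-based cluster-number choice.

PCA treats samples as observations and miRNAs as (centered, unscaled)
variables of the log2-CPM matrix.  The optimal number of clusters is the
k in 2..k_max maximizing the average silhouette width of agglomerative
hierarchical clusterings cut at each k, under correlation distances
(1 - Pearson r and 1 - Spearman rho between samples).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .normalization import NormalizedExpression

DISTANCE_METHODS = ("pearson", "spearman")


@dataclasses.dataclass
class PCAScores:
    scores: pd.DataFrame              # samples x components
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12):
            raise ValueError("explained-variance fractions must be non-increasing")


@dataclasses.dataclass
class SilhouetteProfile:
    """Average silhouette width per (distance method, k) and the chosen k."""

    widths: pd.DataFrame   # index k, columns distance methods, values in [-1, 1]
    chosen_k: dict[str, int]

    def __post_init__(self) -> None:
        vals = self.widths.to_numpy()
        if np.any(vals < -1 - 1e-12) or np.any(vals > 1 + 1e-12):
            raise ValueError("silhouette widths must lie in [-1, 1]")
        for method, k in self.chosen_k.items():
            col = self.widths[method]
            if not np.isclose(col.loc[k], col.max()):
                raise ValueError(f"chosen_k for {method!r} must attain the maximum")


def pca_scores(
    expr: NormalizedExpression | pd.DataFrame,
    subset: Sequence[str] | None = None,
    n_components: int = 2,
) -> PCAScores:
    """Principal-component scores of samples over a miRNA subset.

    Variables (miRNAs) are centered but not scaled; scores come from the
    eigendecomposition of the sample covariance (via SVD of the centered
    matrix).  Component signs are fixed so the largest-magnitude loading
    of each component is positive.
    """
    mat = expr.log2cpm if isinstance(expr, NormalizedExpression) else expr
    if subset is not None:
        missing = [m for m in subset if m not in mat.index]
        if missing:
            raise ValueError(f"miRNAs absent from expression matrix: {missing}")
        if len(subset) == 0:
            raise ValueError("subset must be non-empty")
        mat = mat.loc[list(subset)]
    X = mat.to_numpy(dtype=float).T  # samples x miRNAs
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest |loading| positive per component
    for i in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    var = s**2 / (n - 1)
    total = var.sum()
    evr = var / total if total > 0 else np.zeros_like(var)
    ncomp = min(n_components, s.size)
    scores = pd.DataFrame(
        (u * s)[:, :ncomp],
        index=mat.columns,
        columns=[f"PC{i + 1}" for i in range(ncomp)],
    )
    return PCAScores(scores=scores, explained_variance_ratio=evr[:ncomp])


def correlation_distance(
    expr: NormalizedExpression | pd.DataFrame, method: str = "pearson"
) -> pd.DataFrame:
    """Sample x sample distance matrix d(i,j) = 1 - r(i,j).

    The correlation is computed across miRNAs; ``method`` is "pearson" or
    "spearman" (Pearson on within-sample ranks).  Values lie in [0, 2],
    the diagonal is 0, and a zero-variance sample is an error.
    """
    if method not in DISTANCE_METHODS:
        raise ValueError(f"unknown method {method!r}; use {DISTANCE_METHODS}")
    mat = expr.log2cpm if isinstance(expr, NormalizedExpression) else expr
    X = mat.to_numpy(dtype=float).T  # samples x miRNAs
    if method == "spearman":
        X = np.apply_along_axis(rankdata, 1, X)
    sd = X.std(axis=1)
    flat = [mat.columns[i] for i in np.nonzero(sd == 0)[0]]
    if flat:
        raise ValueError(f"zero-variance samples: {flat}")
    r = np.corrcoef(X)
    d = np.clip(1.0 - r, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=mat.columns, columns=mat.columns)


def silhouette_widths(dist: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-sample silhouette widths from a precomputed distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) where a is the mean distance to
    the other members of i's cluster and b the smallest mean distance to
    any other cluster.  Members of singleton clusters get s(i) = 0.
    """
    dist = np.asarray(dist, dtype=float)
    labels = np.asarray(labels)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("distance matrix must be square")
    uniq = np.unique(labels)
    masks = {c: labels == c for c in uniq}
    sizes = {c: int(m.sum()) for c, m in masks.items()}
    s = np.zeros(n)
    for i in range(n):
        c = labels[i]
        if sizes[c] == 1:
            continue
        a = dist[i, masks[c]].sum() / (sizes[c] - 1)
        b = min(
            dist[i, masks[o]].mean() for o in uniq if o != c
        )
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def estimate_optimal_k(
    expr: NormalizedExpression | pd.DataFrame,
    k_max: int = 10,
    subset: Sequence[str] | None = None,
    linkage_method: str = "average",
    methods: Sequence[str] = DISTANCE_METHODS,
) -> SilhouetteProfile:
    """Average-silhouette profile over k = 2..k_max for each distance method.

    Agglomerative hierarchical clustering (``linkage_method``, default
    average linkage) on each correlation distance matrix is cut at every
    k; chosen_k is the argmax of the average silhouette width, with ties
    resolved toward the smallest k.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    mat = expr.log2cpm if isinstance(expr, NormalizedExpression) else expr
    if subset is not None:
        missing = [m for m in subset if m not in mat.index]
        if missing:
            raise ValueError(f"miRNAs absent from expression matrix: {missing}")
        mat = mat.loc[list(subset)]
    n_samples = mat.shape[1]
    if k_max >= n_samples:
        raise ValueError("k_max must be smaller than the number of samples")

    ks = list(range(2, k_max + 1))
    widths = {}
    chosen = {}
    for method in methods:
        d = correlation_distance(mat, method).to_numpy()
        z = linkage(squareform(d, checks=False), method=linkage_method)
        col = []
        for k in ks:
            labels = fcluster(z, t=k, criterion="maxclust")
            col.append(float(silhouette_widths(d, labels).mean()))
        widths[method] = col
        chosen[method] = ks[int(np.argmax(col))]  # argmax -> smallest on tie
    return SilhouetteProfile(
        widths=pd.DataFrame(widths, index=pd.Index(ks, name="k")),
        chosen_k=chosen,
    )
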