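"""Spot QC, log normalization, highly-variable genes, and domain labeling.

QC keeps spots with at least 163 total UMIs; expression is log-transformed as
``Ei = log(UMI + 1)`` (natural log); highly-variable genes are ranked by
per-gene variance of Ei across spots. Domain labels can be supplied
externally (the first-class path) or produced by the plumbing labeler here:
PCA of the HVG submatrix to 30 components followed by k-means. The plumbing
labeler is a stand-in for graph-based clustering, good enough to exercise
the geometry and interaction stages on synthetic scenes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .matrix import CountMatrix, ExpressionMatrix, NormalizedMatrix

DEFAULT_MIN_UMI = 163
DEFAULT_N_HVG = 2000
DEFAULT_N_COMPONENTS = 30


def filter_spots(counts: CountMatrix, min_umi: int = DEFAULT_MIN_UMI) -> CountMatrix:
    """Keep spots whose total UMI count is at least ``min_umi``."""
    if min_umi < 0:
        raise ValueError("min_umi must be >= 0")
    totals = counts.spot_totals()
    keep = totals.index[totals.to_numpy() >= min_umi]
    return counts.subset_spots(keep)


def log_normalize(counts) -> NormalizedMatrix:
    """Per-entry log abundance Ei = log(count + 1).

    Accepts a :class:`CountMatrix` (returns a :class:`NormalizedMatrix`) or a
    plain array (returns an array) as a real-valued test hook. Preserves the
    sparsity pattern exactly: an entry is 0 iff the source count is 0.
    """
    if isinstance(counts, ExpressionMatrix):
        X = counts.X.copy().astype(np.float64)
        if X.nnz and np.any(X.data < 0):
            raise ValueError("negative counts cannot be log-normalized")
        X.data = np.log1p(X.data)
        return NormalizedMatrix(counts.genes, counts.spots, X)
    arr = np.asarray(counts, dtype=float)
    if np.any(arr < 0):
        raise ValueError("negative counts cannot be log-normalized")
    return np.log1p(arr)


def gene_variances(norm: ExpressionMatrix) -> pd.Series:
    """Per-gene population variance of expression across spots."""
    X = norm.X
    n = X.shape[1]
    mean = np.asarray(X.mean(axis=1)).ravel()
    mean_sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    var = np.maximum(mean_sq - mean**2, 0.0)
    return pd.Series(var, index=norm.genes)


def select_hvg(norm: ExpressionMatrix, n: int = DEFAULT_N_HVG) -> list[str]:
    """The ``n`` genes of largest variance, descending; ties broken by name."""
    if n > norm.n_genes:
        raise ValueError(f"n={n} exceeds gene count {norm.n_genes}")
    var = gene_variances(norm)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:n]


def embed_spots(
    norm: ExpressionMatrix,
    n_components: int = DEFAULT_N_COMPONENTS,
    hvgs: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Principal-component embedding of the (HVG-restricted) spot profiles.

    Each spot profile is centered on its own mean before PCA: per-spot depth
    (spots hold 1-6 cells, so totals vary several-fold) otherwise dominates
    the leading component and masks cell-type structure.
    """
    sub = norm.subset_genes(hvgs) if hvgs is not None else norm
    X = sub.to_dense().T  # spots x genes
    X = X - X.mean(axis=1, keepdims=True)
    n_components = min(n_components, min(X.shape) - 1) or 1
    pcs = PCA(n_components=n_components, random_state=seed).fit_transform(X)
    return pd.DataFrame(pcs, index=norm.spots, columns=[f"PC{i+1}" for i in range(pcs.shape[1])])


def embed_and_label(
    norm: ExpressionMatrix,
    k: int,
    n_components: int = DEFAULT_N_COMPONENTS,
    seed: int = 0,
    hvgs: list[str] | None = None,
) -> pd.Series:
    """Plumbing domain labeler: PCA then k-means into ``k`` labels.

    Returns a spot -> label Series with labels ``domain_0 .. domain_{k-1}``.
    Deterministic under ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > norm.n_spots:
        raise ValueError(f"k={k} exceeds spot count {norm.n_spots}")
    if k == norm.n_spots:
        labels = np.arange(k)
    else:
        pcs = embed_spots(norm, n_components=n_components, hvgs=hvgs, seed=seed)
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(pcs.to_numpy())
    return pd.Series(
        [f"domain_{i}" for i in labels],
        index=pd.Index(norm.spots, name="barcode"),
        name="label",
    )
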