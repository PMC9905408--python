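"""Unbiased co-expression module detection.

Modules are found by k-means on the rows of the gene-gene Pearson
correlation matrix of the highly-variable genes, so genes land in the same
module when they are correlated with the same partners. Module maps average
member-gene expression per spot and time point; submodules come from
average-linkage hierarchical clustering on the ``1 - r`` distance within a
module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_K_MODULES = 18
DEFAULT_CUT_HEIGHT = 0.5


@dataclass
class GeneModule:
    """A co-expression module: 1-based id (1 = largest) and member genes."""

    module_id: int
    genes: list[str]

    def __len__(self) -> int:
        return len(self.genes)


def gene_correlation(norm: ExpressionMatrix, genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Gene x gene Pearson correlation across spots.

    Zero-variance genes are flagged with a logged warning and given
    correlation 0 to every other gene (diagonal stays 1).
    """
    sub = norm.subset_genes(genes) if genes is not None else norm
    if sub.n_spots < 2:
        raise ValueError("correlation requires at least 2 spots")
    X = sub.to_dense()
    Xc = X - X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning("%d zero-variance genes set to correlation 0", int(degenerate.sum()))
    denom = np.where(degenerate, 1.0, sd)
    Z = Xc / denom[:, None]
    corr = (Z @ Z.T) / X.shape[1]
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    return pd.DataFrame(corr, index=sub.genes, columns=sub.genes)


def kmeans_modules(
    correlation: pd.DataFrame, k: int = DEFAULT_K_MODULES, seed: int = 0
) -> list[GeneModule]:
    """Partition genes into ``k`` modules by k-means on correlation rows.

    Module ids are assigned 1..k in order of descending module size
    (ties broken by the lexicographically smallest member gene).
    """
    genes = list(correlation.index)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds gene count {len(genes)}")
    if k == len(genes):
        assign = np.arange(len(genes))
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        assign = km.fit_predict(correlation.to_numpy())
    members: dict[int, list[str]] = {}
    for g, a in zip(genes, assign):
        members.setdefault(int(a), []).append(g)
    ordered = sorted(members.values(), key=lambda gs: (-len(gs), min(gs)))
    return [GeneModule(module_id=i + 1, genes=gs) for i, gs in enumerate(ordered)]


def module_spatiotemporal_map(
    module: GeneModule, norm_by_time: Mapping[int, ExpressionMatrix]
) -> pd.DataFrame:
    """Average member-gene expression per spot at each time point.

    Returns a long table with columns ``time_dpi, barcode, mean_expression``.
    """
    rows = []
    for t in sorted(norm_by_time):
        norm = norm_by_time[t]
        missing = [g for g in module.genes if g not in norm.genes]
        if missing:
            raise KeyError(f"module genes absent at {t} dpi: {missing[:5]}")
        sub = norm.subset_genes(module.genes)
        mean = np.asarray(sub.X.mean(axis=0)).ravel()
        rows.append(pd.DataFrame({"time_dpi": t, "barcode": sub.spots, "mean_expression": mean}))
    return pd.concat(rows, ignore_index=True)


def submodule_hierarchy(
    module: GeneModule,
    correlation: pd.DataFrame,
    cut_height: float = DEFAULT_CUT_HEIGHT,
) -> tuple[np.ndarray, dict[str, list[str]]]:
    """Average-linkage dendrogram and flat submodules within a module.

    Distance is ``1 - r`` on the module's correlation submatrix; flat
    submodules are cut at ``cut_height`` and labeled ``"<id>.1", "<id>.2",
    ...`` in order of descending size (ties by smallest member gene).
    """
    if len(module) < 2:
        raise ValueError("submodule hierarchy requires a module of size >= 2")
    sub = correlation.loc[module.genes, module.genes].to_numpy()
    dist = 1.0 - sub
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    flat = fcluster(Z, t=cut_height, criterion="distance")
    groups: dict[int, list[str]] = {}
    for g, a in zip(module.genes, flat):
        groups.setdefault(int(a), []).append(g)
    ordered = sorted(groups.values(), key=lambda gs: (-len(gs), min(gs)))
    submodules = {f"{module.module_id}.{i + 1}": gs for i, gs in enumerate(ordered)}
    return Z, submodules


def modules_to_frame(modules: Sequence[GeneModule]) -> pd.DataFrame:
    """Gene -> module table for serialization."""
    rows = [(g, m.module_id) for m in modules for g in m.genes]
    return pd.DataFrame(rows, columns=["gene", "module_id"])
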