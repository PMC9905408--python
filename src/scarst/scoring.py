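"""Per-spot gene-set scoring and distance-resolved layer profiles.

Two scores are provided. :func:`module_score` is the control-matched mean
used for cell-type assignment: mean expression of the signature genes minus
the mean of control genes drawn from the same average-expression bins, so a
score near 0 means "no enrichment over expression-matched background".
:func:`pathway_activity` is a single-sample rank statistic for pathway
activity maps: within each spot, genes are ranked by Ei and the score is the
normalized rank-sum difference between set and non-set genes (the integrated
difference of their rank ECDFs, equal to ``2*AUC - 1``), bounded in [-1, 1],
+1 when the set occupies the top ranks and antisymmetric under reversal of
the ranking. It depends on within-spot ranks only.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import EmptyGeneSetError, EmptyRegionError
from .matrix import ExpressionMatrix
from .synthetic import SpotLattice

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 25
DEFAULT_N_CTRL = 100


def module_score(
    norm: ExpressionMatrix,
    gene_set: Iterable[str],
    n_bins: int = DEFAULT_N_BINS,
    n_ctrl: int = DEFAULT_N_CTRL,
    seed: int = 0,
) -> pd.Series:
    """Control-matched signature score per spot.

    Signature genes are matched to ``n_ctrl`` control genes each, sampled
    without replacement from the same bin of average expression (``n_bins``
    equal-count bins over all genes); the score is the mean signature
    expression minus the mean control expression. Invariant to adding a
    constant to every matrix entry.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    genes_present = [g for g in dict.fromkeys(gene_set) if g in norm.genes]
    if not genes_present:
        raise EmptyGeneSetError("no signature gene is present in the matrix")

    X = norm.to_dense()
    avg = X.mean(axis=1)
    # Equal-count bins of average expression; average ranks keep genes with
    # identical averages (e.g. all-zero genes) in the same bin, so controls
    # for a signature gene always share its expression level.
    avg_rank = rankdata(avg, method="average")
    bins = np.ceil(avg_rank * n_bins / len(avg)).astype(int)

    gene_loc = {g: i for i, g in enumerate(norm.genes)}
    set_idx = np.array([gene_loc[g] for g in genes_present])
    in_set = np.zeros(norm.n_genes, dtype=bool)
    in_set[set_idx] = True

    rng = np.random.default_rng(seed)
    ctrl_idx: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if len(pool) == 0:
            logger.warning("no control genes share the expression bin of %s", norm.genes[gi])
            continue
        take = min(n_ctrl, len(pool))
        ctrl_idx.append(rng.choice(pool, size=take, replace=False))
    if not ctrl_idx:
        raise EmptyGeneSetError("no control genes available in any signature bin")
    ctrl = np.concatenate(ctrl_idx)

    score = X[set_idx].mean(axis=0) - X[ctrl].mean(axis=0)
    return pd.Series(score, index=norm.spots, name="module_score")


def assign_cell_types(
    score_maps: Mapping[str, pd.Series], labels: pd.Series
) -> dict[str, str]:
    """Assign each cluster label the cell type with the highest mean score.

    Ties are broken by cell-type name order, with a logged warning.
    """
    if not score_maps:
        raise ValueError("at least one score map is required")
    assignment: dict[str, str] = {}
    cell_types = sorted(score_maps)
    for label in sorted(labels.unique()):
        spots = labels.index[labels == label]
        means = {ct: float(score_maps[ct].loc[spots].mean()) for ct in cell_types}
        best = max(means.values())
        winners = [ct for ct in cell_types if means[ct] == best]
        if len(winners) > 1:
            logger.warning("cluster %s: tied cell-type scores %s; keeping %s", label, winners, winners[0])
        assignment[label] = winners[0]
    return assignment


def pathway_activity(norm: ExpressionMatrix, gene_set: Iterable[str]) -> pd.Series:
    """Single-sample rank-based pathway activity per spot, in [-1, 1]."""
    genes_present = [g for g in dict.fromkeys(gene_set) if g in norm.genes]
    if not genes_present:
        raise EmptyGeneSetError("no pathway gene is present in the matrix")
    m = len(genes_present)
    G = norm.n_genes
    if m >= G:
        raise ValueError("gene set covers every gene; the statistic is undefined")

    X = norm.to_dense()
    ranks = rankdata(X, method="average", axis=0)  # per spot; 1 = lowest Ei
    in_set = norm.genes.isin(genes_present)
    mean_in = ranks[in_set].mean(axis=0)
    mean_out = ranks[~in_set].mean(axis=0)
    score = 2.0 * (mean_in - mean_out) / G
    return pd.Series(score, index=norm.spots, name="pathway_activity")


def layer_profile(
    score_map: pd.Series,
    layers: pd.Series,
    layer_index: int,
    center_um: tuple[float, float],
    lattice: SpotLattice,
    axis: str = "col",
) -> pd.DataFrame:
    """Mean score vs. signed spot-distance from the scar center, in one layer.

    Spots of the layer are binned by signed distance from the center along
    the ``axis`` direction (``col`` = x, the direction running along the
    layer when layers are row bands), in units of one lattice pitch; halves
    round away from zero so the binning is mirror-symmetric. Returns one row
    per integer bin from -R to +R with the bin's mean score and population.
    """
    spots = layers.index[layers == layer_index]
    if len(spots) == 0:
        raise EmptyRegionError(f"layer {layer_index} contains no spots")
    pos = lattice.positions_frame().loc[spots]
    coord = pos["x_um"] if axis == "col" else pos["y_um"]
    c = center_um[0] if axis == "col" else center_um[1]
    d = (coord - c) / lattice.pitch_um
    bins = (np.sign(d) * np.floor(np.abs(d) + 0.5)).astype(int)

    scores = score_map.loc[spots]
    df = pd.DataFrame({"bin": bins, "score": scores})
    grouped = df.groupby("bin")["score"].agg(["mean", "size"])
    r = int(np.abs(bins).max())
    full = pd.DataFrame(index=pd.RangeIndex(-r, r + 1, name="bin"))
    full["mean_score"] = grouped["mean"]
    full["n_spots"] = grouped["size"].reindex(full.index).fillna(0).astype(int)
    full["distance_um"] = full.index * lattice.pitch_um
    return full.reset_index()[["bin", "distance_um", "mean_score", "n_spots"]]
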