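"""Boundary-restricted ligand-receptor interaction testing.

For every ordered pair of spatially adjacent domains, the test is run on the
2-spot-wide interface bands flanking their boundary: a pair is considered
only if the ligand is expressed (Ei > 0) in more than a threshold fraction
(default 0.1) of the ligand-side spots and likewise the receptor on the
receptor side; its score is the mean of the two cluster averages (mean
ligand Ei on the source side and mean receptor Ei on the target side); and
its p-value is the proportion of label permutations whose score is equal to
or higher than the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyRegionError
from .geometry import DEFAULT_INTERFACE_WIDTH, domain_adjacency, extract_interface
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.1
DEFAULT_N_PERM = 1000


@dataclass(frozen=True)
class LRPair:
    """A ligand gene and its cognate receptor gene."""

    ligand_gene: str
    receptor_gene: str

    @property
    def pair_name(self) -> str:
        return f"{self.ligand_gene}_{self.receptor_gene}"


@dataclass
class InteractionResult:
    """Outcome of one LR pair tested on one ordered cluster pair.

    ``p_value`` is the plain permutation proportion (0 attainable);
    ``p_conservative`` is the (k+1)/(n+1) estimator. ``p_value`` is ``None``
    for pairs that failed the expression-fraction filter.
    """

    pair: LRPair
    source_cluster: str
    target_cluster: str
    mean_score: float
    ligand_fraction: float
    receptor_fraction: float
    p_value: float | None = None
    p_conservative: float | None = None
    n_permutations: int = 0


def expression_fraction(norm: ExpressionMatrix, gene: str, spot_set: Iterable) -> float:
    """Fraction of the given spots in which the gene is expressed (Ei > 0)."""
    spots = list(spot_set)
    if not spots:
        raise EmptyRegionError("expression_fraction over an empty spot set")
    expr = norm.gene_vector(gene).loc[spots]
    return float((expr.to_numpy() > 0).mean())


def pair_filter(
    ligand_fraction: float, receptor_fraction: float, threshold: float = DEFAULT_THRESHOLD
) -> bool:
    """True iff both fractions strictly exceed the threshold."""
    return ligand_fraction > threshold and receptor_fraction > threshold


def interaction_score(
    norm: ExpressionMatrix, pair: LRPair, ligand_spots: Iterable, receptor_spots: Iterable
) -> float:
    """Mean of the ligand-side and receptor-side average expression."""
    lig = list(ligand_spots)
    rec = list(receptor_spots)
    if not lig or not rec:
        raise EmptyRegionError("interaction_score requires non-empty spot sets on both sides")
    lig_mean = float(norm.gene_vector(pair.ligand_gene).loc[lig].mean())
    rec_mean = float(norm.gene_vector(pair.receptor_gene).loc[rec].mean())
    return (lig_mean + rec_mean) / 2.0


def _perm_pvalue(
    lig_expr: np.ndarray,
    rec_expr: np.ndarray,
    n_src: int,
    observed: float,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation p-values for the two-mean score on pooled spots.

    ``lig_expr``/``rec_expr`` are the two genes' expression over the pooled
    spots (source spots first). Scores equal to the observed one count as
    extreme; equality is tested with a small tolerance so that a constant
    gene yields p = 1 regardless of float summation order.
    """
    n_pool = len(lig_expr)
    idx = np.tile(np.arange(n_pool), (n_perm, 1))
    idx = rng.permuted(idx, axis=1)
    perm = lig_expr[idx[:, :n_src]].mean(axis=1) / 2.0 + rec_expr[idx[:, n_src:]].mean(axis=1) / 2.0
    tol = 1e-9 * max(1.0, abs(observed))
    k = int(np.count_nonzero(perm >= observed - tol))
    return k / n_perm, (k + 1) / (n_perm + 1)


def permutation_pvalue(
    norm: ExpressionMatrix,
    pair: LRPair,
    ligand_spots: Sequence,
    receptor_spots: Sequence,
    source_cluster: str = "source",
    target_cluster: str = "target",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
) -> InteractionResult:
    """Label-permutation test of one LR pair between two spot sets.

    Cluster labels are shuffled uniformly over the pooled spots, preserving
    group sizes; p is the proportion of permuted scores >= the observed
    score. Deterministic under ``seed``.
    """
    lig_spots = list(ligand_spots)
    rec_spots = list(receptor_spots)
    if len(lig_spots) < 2 or len(rec_spots) < 2:
        raise EmptyRegionError("permutation test requires >= 2 spots on each side")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pooled = lig_spots + rec_spots
    lig_expr = norm.gene_vector(pair.ligand_gene).loc[pooled].to_numpy()
    rec_expr = norm.gene_vector(pair.receptor_gene).loc[pooled].to_numpy()
    n_src = len(lig_spots)
    observed = lig_expr[:n_src].mean() / 2.0 + rec_expr[n_src:].mean() / 2.0
    p, p_cons = _perm_pvalue(lig_expr, rec_expr, n_src, observed, n_perm, rng)
    return InteractionResult(
        pair=pair,
        source_cluster=source_cluster,
        target_cluster=target_cluster,
        mean_score=float(observed),
        ligand_fraction=expression_fraction(norm, pair.ligand_gene, lig_spots),
        receptor_fraction=expression_fraction(norm, pair.receptor_gene, rec_spots),
        p_value=p,
        p_conservative=p_cons,
        n_permutations=n_perm,
    )


def run_boundary_lr(
    norm: ExpressionMatrix,
    labels: pd.Series,
    graph: nx.Graph,
    pairs: Sequence[LRPair],
    width: int = DEFAULT_INTERFACE_WIDTH,
    threshold: float = DEFAULT_THRESHOLD,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    scope: str = "interface",
) -> list[InteractionResult]:
    """Run the LR test for every ordered adjacent cluster pair.

    ``scope`` controls the permutation universe and scoring spots:
    ``"interface"`` (default) restricts both to the 2-spot-wide boundary
    bands; ``"cluster"`` uses all spots of the two clusters. Both orderings
    of each adjacent pair are tested (ligand on one side, then the other).
    Pairs failing the expression filter are reported with ``p_value=None``.
    """
    if scope not in ("interface", "cluster"):
        raise ValueError("scope must be 'interface' or 'cluster'")
    rng = np.random.default_rng(seed)
    results: list[InteractionResult] = []
    adjacent = sorted(domain_adjacency(labels, graph))
    for a, b in adjacent:
        region = extract_interface(labels, graph, a, b, width=width)
        for src, tgt in ((a, b), (b, a)):
            if scope == "interface":
                src_spots = sorted(region.spots_a if src == a else region.spots_b)
                tgt_spots = sorted(region.spots_b if src == a else region.spots_a)
            else:
                src_spots = sorted(labels.index[labels == src])
                tgt_spots = sorted(labels.index[labels == tgt])
            if len(src_spots) < 2 or len(tgt_spots) < 2:
                logger.info("skipping %s->%s: fewer than 2 spots on a side", src, tgt)
                continue
            for pair in pairs:
                lig_frac = expression_fraction(norm, pair.ligand_gene, src_spots)
                rec_frac = expression_fraction(norm, pair.receptor_gene, tgt_spots)
                if not pair_filter(lig_frac, rec_frac, threshold):
                    results.append(
                        InteractionResult(
                            pair=pair,
                            source_cluster=src,
                            target_cluster=tgt,
                            mean_score=interaction_score(norm, pair, src_spots, tgt_spots),
                            ligand_fraction=lig_frac,
                            receptor_fraction=rec_frac,
                        )
                    )
                    continue
                results.append(
                    permutation_pvalue(
                        norm,
                        pair,
                        src_spots,
                        tgt_spots,
                        source_cluster=src,
                        target_cluster=tgt,
                        n_perm=n_perm,
                        seed=rng,
                    )
                )
    return results


def results_to_frame(results: Sequence[InteractionResult]) -> pd.DataFrame:
    """Flatten results into the dot-plot table (rows = pairs x cluster pairs)."""
    return pd.DataFrame(
        {
            "pair": [r.pair.pair_name for r in results],
            "ligand": [r.pair.ligand_gene for r in results],
            "receptor": [r.pair.receptor_gene for r in results],
            "source_cluster": [r.source_cluster for r in results],
            "target_cluster": [r.target_cluster for r in results],
            "mean_score": [r.mean_score for r in results],
            "ligand_fraction": [r.ligand_fraction for r in results],
            "receptor_fraction": [r.receptor_fraction for r in results],
            "p_value": [r.p_value for r in results],
            "p_conservative": [r.p_conservative for r in results],
            "n_permutations": [r.n_permutations for r in results],
        }
    )
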