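"""Gene-by-spot expression containers.

A :class:`CountMatrix` holds raw UMI counts (nonnegative integers) and a
:class:`NormalizedMatrix` holds per-spot log abundances ``Ei = log(UMI + 1)``.
Both are thin wrappers around a sparse genes x spots matrix plus ordered name
lists, mirroring the CellRanger convention (genes are Matrix Market rows).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class ExpressionMatrix:
    """Ordered genes x spots matrix with unique name lists.

    Parameters
    ----------
    genes, spots
        Ordered unique identifiers for rows and columns.
    values
        Dense or sparse 2-D array of shape ``(len(genes), len(spots))``.
    """

    def __init__(self, genes: Sequence[str], spots: Sequence[str], values) -> None:
        genes = pd.Index(genes, dtype=object)
        spots = pd.Index(spots, dtype=object)
        if not genes.is_unique:
            raise ValueError("gene names must be unique")
        if not spots.is_unique:
            raise ValueError("spot identifiers must be unique")
        X = sp.csr_matrix(values)
        if X.shape != (len(genes), len(spots)):
            raise ValueError(
                f"matrix shape {X.shape} does not match {len(genes)} genes x {len(spots)} spots"
            )
        self.genes = genes
        self.spots = spots
        self.X = X

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_spots(self) -> int:
        return self.X.shape[1]

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.X.todense())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_dense(), index=self.genes, columns=self.spots)

    def gene_vector(self, gene: str) -> pd.Series:
        """Expression of one gene across all spots."""
        i = self.genes.get_loc(gene)
        return pd.Series(
            np.asarray(self.X[i, :].todense()).ravel(), index=self.spots, name=gene
        )

    def spot_totals(self) -> pd.Series:
        """Per-spot sum over genes (total UMIs for a CountMatrix)."""
        return pd.Series(np.asarray(self.X.sum(axis=0)).ravel(), index=self.spots)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        idx = self.genes.get_indexer(list(genes))
        if (idx < 0).any():
            missing = [g for g, i in zip(list(genes), idx) if i < 0]
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        return type(self)(self.genes[idx], self.spots, self.X[idx, :])

    def subset_spots(self, spots: Iterable[str]) -> "ExpressionMatrix":
        idx = self.spots.get_indexer(list(spots))
        if (idx < 0).any():
            missing = [s for s, i in zip(list(spots), idx) if i < 0]
            raise KeyError(f"spots not in matrix: {missing[:5]}")
        return type(self)(self.genes, self.spots[idx], self.X[:, idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.genes.equals(other.genes)
            and self.spots.equals(other.spots)
            and (self.X != other.X).nnz == 0
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"{type(self).__name__}({self.n_genes} genes x {self.n_spots} spots)"


class CountMatrix(ExpressionMatrix):
    """Raw UMI counts: nonnegative integers."""

    def __init__(self, genes, spots, values) -> None:
        super().__init__(genes, spots, values)
        if self.X.nnz:
            data = self.X.data
            if np.any(data < 0):
                raise ValueError("count matrix contains negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValueError("count matrix contains non-integer entries")
        self.X = self.X.astype(np.int64)


class NormalizedMatrix(ExpressionMatrix):
    """Log-transformed abundances Ei = log(UMI + 1); nonnegative reals."""

    def __init__(self, genes, spots, values) -> None:
        super().__init__(genes, spots, values)
        if self.X.nnz and np.any(self.X.data < 0):
            raise ValueError("normalized matrix contains negative entries")
        self.X = self.X.astype(np.float64)
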