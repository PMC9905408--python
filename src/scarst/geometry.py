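"""Spatial structure of the lesion.

Builds the hexagonal neighbor graph, locates the scar center and radius,
cuts the section into layers, extracts the 2-spot-wide interface bands along
domain boundaries, and tallies per-time-point cell-type fractions over the
scar. Distances between spots for interface extraction are lattice-graph
step counts (breadth-first search), not Euclidean µm.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptyRegionError
from .synthetic import SpotLattice

DEFAULT_INTERFACE_WIDTH = 2
DEFAULT_N_LAYERS = 4


@dataclass(frozen=True)
class InterfaceRegion:
    """The two bands of spots flanking a boundary between two domains.

    ``spots_a``/``spots_b`` are the spots of each cluster lying within
    ``width`` lattice steps of the opposite cluster.
    """

    cluster_a: str
    cluster_b: str
    spots_a: frozenset
    spots_b: frozenset
    width: int

    @property
    def all_spots(self) -> frozenset:
        return self.spots_a | self.spots_b

    def __bool__(self) -> bool:
        return bool(self.spots_a or self.spots_b)


def neighbor_graph(lattice: SpotLattice) -> nx.Graph:
    """Undirected graph joining spot pairs exactly one pitch apart."""
    g = nx.Graph()
    g.add_nodes_from(lattice.spot_ids)
    coords = lattice.coords()
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=lattice.pitch_um + 1e-6, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        ok = np.abs(d - lattice.pitch_um) <= 1e-6
        g.add_edges_from(
            (lattice.spot_ids[i], lattice.spot_ids[j]) for i, j in pairs[ok]
        )
    return g


def scar_center(
    labels: pd.Series, lattice: SpotLattice, scar_labels: Iterable[str]
) -> tuple[float, float]:
    """Centroid (mean x, mean y in µm) of the scar-labeled spots."""
    scar_labels = set(scar_labels)
    pos = lattice.positions_frame()
    mask = labels[labels.isin(scar_labels)].index
    if len(mask) == 0:
        raise EmptyRegionError(f"no spot carries a scar label from {sorted(scar_labels)}")
    sub = pos.loc[mask]
    return float(sub["x_um"].mean()), float(sub["y_um"].mean())


def scar_radius_spots(
    labels: pd.Series, lattice: SpotLattice, scar_labels: Iterable[str]
) -> tuple[float, int]:
    """Scar extent: max distance (µm) from the scar centroid, and in spots.

    The spot radius is ``ceil(radius_um / pitch_um)``; 1.2 mm at the 100-µm
    pitch maps to 12 spots.
    """
    cx, cy = scar_center(labels, lattice, scar_labels)
    pos = lattice.positions_frame()
    mask = labels[labels.isin(set(scar_labels))].index
    sub = pos.loc[mask]
    radius = float(np.hypot(sub["x_um"] - cx, sub["y_um"] - cy).max())
    return radius, math.ceil(round(radius / lattice.pitch_um, 9))


def assign_layers(
    lattice: SpotLattice, n_layers: int = DEFAULT_N_LAYERS, axis: str = "row"
) -> pd.Series:
    """Cut the occupied area into equal-width bands perpendicular to ``axis``.

    ``axis="row"`` bands along the row (y) direction, ``axis="col"`` along
    the column (x) direction. Layers are indexed 1..n_layers.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if axis not in ("row", "col"):
        raise ValueError("axis must be 'row' or 'col'")
    coord = lattice.y_um if axis == "row" else lattice.x_um
    lo, hi = float(coord.min()), float(coord.max())
    if n_layers == 1 or hi == lo:
        layer = np.ones(lattice.n_spots, dtype=int)
    else:
        width = (hi - lo) / n_layers
        layer = np.minimum((coord - lo) // width, n_layers - 1).astype(int) + 1
    return pd.Series(layer, index=pd.Index(lattice.spot_ids, name="barcode"), name="layer")


def _bfs_distances(graph: nx.Graph, sources: Iterable, cutoff: int) -> dict:
    """Multi-source BFS step distances up to ``cutoff``."""
    dist = {s: 0 for s in sources}
    frontier = deque(dist)
    while frontier:
        u = frontier.popleft()
        if dist[u] == cutoff:
            continue
        for v in graph.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                frontier.append(v)
    return dist


def extract_interface(
    labels: pd.Series,
    graph: nx.Graph,
    cluster_a: str,
    cluster_b: str,
    width: int = DEFAULT_INTERFACE_WIDTH,
) -> InterfaceRegion:
    """Spots of each cluster within ``width`` lattice steps of the other.

    Returns an empty region (not an error) when the clusters are farther
    than ``width`` steps apart.
    """
    present = set(labels.unique())
    for c in (cluster_a, cluster_b):
        if c not in present:
            raise ValueError(f"unknown cluster label {c!r}")
    if width < 1:
        raise ValueError("width must be >= 1")
    a_spots = set(labels.index[labels == cluster_a])
    b_spots = set(labels.index[labels == cluster_b])
    dist_to_b = _bfs_distances(graph, b_spots, width)
    dist_to_a = _bfs_distances(graph, a_spots, width)
    return InterfaceRegion(
        cluster_a=cluster_a,
        cluster_b=cluster_b,
        spots_a=frozenset(s for s in a_spots if s in dist_to_b and dist_to_b[s] <= width),
        spots_b=frozenset(s for s in b_spots if s in dist_to_a and dist_to_a[s] <= width),
        width=width,
    )


def domain_adjacency(labels: pd.Series, graph: nx.Graph) -> set[tuple[str, str]]:
    """Unordered label pairs joined by at least one lattice edge."""
    pairs: set[tuple[str, str]] = set()
    lab = labels.to_dict()
    for u, v in graph.edges:
        lu, lv = lab.get(u), lab.get(v)
        if lu is None or lv is None or lu == lv:
            continue
        pairs.add(tuple(sorted((lu, lv))))
    return pairs


def celltype_fractions(
    labels_by_time: Mapping[int, pd.Series],
    scar_spots_by_time: Mapping[int, Iterable] | None = None,
) -> pd.DataFrame:
    """Spot counts and fractions per cell type per time point over the scar.

    ``scar_spots_by_time`` restricts the tally to the scar region at each
    time point; when omitted, all labeled spots are counted.
    """
    rows = []
    for t in sorted(labels_by_time):
        lab = labels_by_time[t]
        if scar_spots_by_time is not None:
            lab = lab.loc[lab.index.intersection(pd.Index(list(scar_spots_by_time[t])))]
        if lab.empty:
            raise EmptyRegionError(f"no scar spots at time {t} dpi")
        total = len(lab)
        for cell_type, n in lab.value_counts().sort_index().items():
            rows.append(
                {"time_dpi": t, "cell_type": cell_type, "n_spots": int(n), "fraction": n / total}
            )
    return pd.DataFrame(rows, columns=["time_dpi", "cell_type", "n_spots", "fraction"])
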