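"""Synthetic Visium-like lesions with known ground truth.

The generator emulates what a hemisection scar looks like on a barcoded spot
array: a hexagonally packed lattice (100-µm pitch, 55-µm spots), concentric
time-varying cellular domains (a macrophage-dominated core in the early acute
stage; later a fibrotic core wrapped by microglial, astrocytic and
oligodendrocyte rings inside neuronal gray matter), 1-6 cells per spot, and
negative-binomial UMI counts driven by per-cell-type marker programs.
Ligand-receptor pairs and co-expression blocks can be planted so downstream
statistics can be benchmarked against a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .matrix import CountMatrix

# Cell types of the mature scar, ordered core -> periphery.
SCAR_CELL_TYPES = (
    "fibroblast",
    "macrophage",
    "microglia",
    "astrocyte",
    "oligodendrocyte",
    "neuron",
)

TIME_POINTS_DPI = (3, 7, 14, 28)


@dataclass(frozen=True)
class SpotLattice:
    """Hexagonally packed capture array.

    Odd array rows are offset by ``pitch_um / 2`` and rows are spaced
    ``pitch_um * sqrt(3) / 2`` apart, so every interior spot has six
    equidistant neighbors at exactly ``pitch_um``.
    """

    spot_ids: np.ndarray
    array_row: np.ndarray
    array_col: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    pitch_um: float
    diameter_um: float

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def coords(self) -> np.ndarray:
        """(n_spots, 2) array of µm coordinates."""
        return np.column_stack([self.x_um, self.y_um])

    def positions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "barcode": self.spot_ids,
                "array_row": self.array_row,
                "array_col": self.array_col,
                "x_um": self.x_um,
                "y_um": self.y_um,
            }
        ).set_index("barcode")

    def center_um(self) -> tuple[float, float]:
        """Geometric center of the occupied bounding box."""
        return (
            float((self.x_um.min() + self.x_um.max()) / 2.0),
            float((self.y_um.min() + self.y_um.max()) / 2.0),
        )

    def nearest_spot(self, x: float, y: float) -> str:
        d2 = (self.x_um - x) ** 2 + (self.y_um - y) ** 2
        return str(self.spot_ids[int(np.argmin(d2))])


@dataclass(frozen=True)
class CellTypeProgram:
    """Expression program of one cell type.

    ``marker_log_fold`` is the natural-log enrichment of the type's marker
    genes over ``baseline_mean`` (the NB mean per cell for every non-marker
    gene); ``dispersion`` is the NB size parameter per cell.
    """

    cell_type: str
    marker_genes: tuple[str, ...]
    marker_log_fold: float = 2.2
    baseline_mean: float = 0.3
    dispersion: float = 2.0

    def __post_init__(self) -> None:
        if not self.marker_genes:
            raise ConfigurationError(f"{self.cell_type}: marker_genes must be non-empty")
        if self.marker_log_fold <= 0 or self.baseline_mean < 0 or self.dispersion <= 0:
            raise ConfigurationError(f"{self.cell_type}: rates must be positive")


@dataclass(frozen=True)
class PlantedInteraction:
    """Ground-truth ligand-receptor pair between two adjacent domains.

    ``effect`` is added to the per-cell NB mean of the ligand gene in
    ``source_type`` and of the receptor gene in ``target_type``.
    """

    ligand_gene: str
    receptor_gene: str
    source_type: str
    target_type: str
    effect: float = 3.0

    def __post_init__(self) -> None:
        if self.source_type == self.target_type:
            raise ConfigurationError("source and target types must differ")
        if self.ligand_gene == self.receptor_gene:
            raise ConfigurationError("ligand and receptor genes must differ")
        if self.effect <= 0:
            raise ConfigurationError("effect must be positive")


@dataclass
class ScarScene:
    """One time point of a synthetic lesion with per-spot ground truth."""

    time_dpi: int
    center_um: tuple[float, float]
    ring_radii_um: tuple[tuple[str, float], ...]
    cells_per_spot: pd.Series
    spot_mixture: pd.DataFrame  # spots x cell types, rows sum to 1
    truth_labels: pd.Series
    lattice: SpotLattice = field(repr=False)

    @property
    def cell_types(self) -> list[str]:
        return list(self.spot_mixture.columns)


# --------------------------------------------------------------------------
# Lattice construction
# --------------------------------------------------------------------------

#: Vendor full-array dimensions: 78 x 64 = 4,992 spots on a 6.5 mm square.
FULL_ARRAY_ROWS = 78
FULL_ARRAY_COLS = 64
DEFAULT_PITCH_UM = 100.0
DEFAULT_DIAMETER_UM = 55.0


def build_lattice(
    n_rows: int = FULL_ARRAY_ROWS,
    n_cols: int = FULL_ARRAY_COLS,
    pitch_um: float = DEFAULT_PITCH_UM,
    diameter_um: float = DEFAULT_DIAMETER_UM,
) -> SpotLattice:
    """Build a hexagonally packed spot lattice.

    The default dimensions reproduce the full capture array: 4,992 spots of
    55 µm diameter at a 100-µm center-to-center distance.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    if not (0 < diameter_um <= pitch_um):
        raise ValueError("require 0 < diameter_um <= pitch_um")
    rows, cols = np.divmod(np.arange(n_rows * n_cols), n_cols)
    x = cols * pitch_um + (rows % 2) * (pitch_um / 2.0)
    y = rows * (pitch_um * math.sqrt(3.0) / 2.0)
    ids = np.array([f"s{r:03d}x{c:03d}" for r, c in zip(rows, cols)], dtype=object)
    return SpotLattice(
        spot_ids=ids,
        array_row=rows.astype(np.int64),
        array_col=cols.astype(np.int64),
        x_um=x.astype(np.float64),
        y_um=y.astype(np.float64),
        pitch_um=float(pitch_um),
        diameter_um=float(diameter_um),
    )


# --------------------------------------------------------------------------
# Scene construction
# --------------------------------------------------------------------------

# Outer ring radii (µm) per time point, core -> periphery. The early acute
# core is macrophage-dominated; from the subacute stage on, fibroblasts hold
# the core and the core shrinks as the scar matures and compacts.
DEFAULT_RING_RADII_UM: dict[int, tuple[tuple[str, float], ...]] = {
    3: (("macrophage", 700.0), ("microglia", 1000.0), ("astrocyte", 1400.0), ("oligodendrocyte", 2000.0)),
    7: (("fibroblast", 600.0), ("microglia", 1000.0), ("astrocyte", 1400.0), ("oligodendrocyte", 2000.0)),
    14: (("fibroblast", 500.0), ("microglia", 900.0), ("astrocyte", 1300.0), ("oligodendrocyte", 1900.0)),
    28: (("fibroblast", 400.0), ("microglia", 800.0), ("astrocyte", 1200.0), ("oligodendrocyte", 1800.0)),
}

#: Cell type occupying everything outside the outermost ring.
BACKGROUND_TYPE = "neuron"

MIN_CELLS_PER_SPOT = 1
MAX_CELLS_PER_SPOT = 6


def make_scene(
    lattice: SpotLattice,
    time_dpi: int,
    seed: int,
    ring_radii_um: Mapping[int, tuple[tuple[str, float], ...]] | None = None,
) -> ScarScene:
    """Generate a concentric scar scene at one time point.

    Each spot's dominant cell type is set by which ring its center falls in;
    the remaining mixture mass is shared with the radially adjacent types,
    emulating the 1-6-cell mixtures a 55-µm spot captures. Output is a pure
    function of ``(lattice, time_dpi, seed)``.
    """
    radii_table = dict(DEFAULT_RING_RADII_UM if ring_radii_um is None else ring_radii_um)
    if time_dpi not in radii_table:
        raise ValueError(f"unsupported time point {time_dpi}; expected one of {sorted(radii_table)}")
    rings = tuple(radii_table[time_dpi])
    radii = [r for _, r in rings]
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ConfigurationError("ring radii must be strictly increasing from the core outward")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(time_dpi), 0x5CA2]))
    center = lattice.center_um()
    dist = np.hypot(lattice.x_um - center[0], lattice.y_um - center[1])

    ordered_types = [t for t, _ in rings] + [BACKGROUND_TYPE]
    edges = np.asarray(radii, dtype=float)
    ring_index = np.searchsorted(edges, dist, side="left")  # 0..len(rings)
    labels = np.asarray(ordered_types, dtype=object)[ring_index]

    all_types = list(dict.fromkeys(ordered_types + list(SCAR_CELL_TYPES)))
    n = lattice.n_spots
    mixture = np.zeros((n, len(all_types)), dtype=float)
    col = {t: j for j, t in enumerate(all_types)}

    # A spot captures a mixture only where its 55-µm footprint straddles a
    # ring edge, so the share of the radially adjacent domain decays with
    # distance from the edge on the scale of the spot radius: straddling
    # spots approach a 50/50 mixture, spots one pitch away are nearly pure.
    # The 0.49 ceiling keeps the dominant weight above every share, so the
    # argmax of the mixture is always the ring label.
    scale = lattice.diameter_um / 2.0
    damp = rng.uniform(0.7, 1.0, size=n)
    for i in range(n):
        k = ring_index[i]
        shares: dict[str, float] = {}
        if k > 0:  # inner edge toward the previous ring
            d_edge = abs(dist[i] - edges[k - 1])
            shares[ordered_types[k - 1]] = 0.49 * damp[i] * math.exp(-((d_edge / scale) ** 2))
        if k < len(ordered_types) - 1:  # outer edge toward the next ring
            d_edge = abs(dist[i] - edges[k])
            shares[ordered_types[k + 1]] = 0.49 * damp[i] * math.exp(-((d_edge / scale) ** 2))
        total = sum(shares.values())
        mixture[i, col[labels[i]]] = 1.0 - total
        for t, s in shares.items():
            mixture[i, col[t]] += s

    cells = rng.integers(MIN_CELLS_PER_SPOT, MAX_CELLS_PER_SPOT + 1, size=n)

    index = pd.Index(lattice.spot_ids, dtype=object, name="barcode")
    return ScarScene(
        time_dpi=int(time_dpi),
        center_um=center,
        ring_radii_um=rings,
        cells_per_spot=pd.Series(cells, index=index, name="cells_per_spot"),
        spot_mixture=pd.DataFrame(mixture, index=index, columns=all_types),
        truth_labels=pd.Series(labels, index=index, name="truth_label"),
        lattice=lattice,
    )


# --------------------------------------------------------------------------
# Default expression programs
# --------------------------------------------------------------------------

#: Canonical spinal-cord marker genes per scar cell type (mouse symbols).
DEFAULT_MARKERS: dict[str, tuple[str, ...]] = {
    "fibroblast": ("Col1a1", "Col1a2", "Col3a1", "Dcn", "Fn1", "Igfbp6"),
    "macrophage": ("Lyz2", "Pf4", "Arg1", "Cd68", "Ccr2", "Thbs1"),
    "microglia": ("P2ry12", "Tmem119", "Cx3cr1", "Gpr37l1", "Csf1r", "Plxnb2"),
    "astrocyte": ("Gfap", "Aqp4", "Slc1a3", "Mt3", "Aldh1l1", "Vim"),
    "oligodendrocyte": ("Plp1", "Mbp", "Mal", "Mog", "Cnp", "Sox10"),
    "neuron": ("Snap25", "Rbfox3", "Syt1", "Meg3", "Nefl", "Gria2"),
}


def default_programs(
    marker_log_fold: float = 2.2, baseline_mean: float = 0.3, dispersion: float = 2.0
) -> list[CellTypeProgram]:
    """One program per scar cell type, using canonical marker symbols."""
    return [
        CellTypeProgram(t, DEFAULT_MARKERS[t], marker_log_fold, baseline_mean, dispersion)
        for t in SCAR_CELL_TYPES
    ]


def default_interactions(effect: float = 3.0) -> list[PlantedInteraction]:
    """Planted ligand-receptor signals across adjacent scar domains.

    The fibroblast-to-microglia Psap/Gpr37l1 axis mirrors signaling reported
    at the fibrotic-core boundary; the rest span the other ring interfaces.
    """
    return [
        PlantedInteraction("Psap", "Gpr37l1", "fibroblast", "microglia", effect),
        PlantedInteraction("Tgfb1", "Tgfbr2", "microglia", "fibroblast", effect),
        PlantedInteraction("Csf1", "Csf1r", "astrocyte", "microglia", effect),
        PlantedInteraction("Apoe", "Lrp1", "astrocyte", "oligodendrocyte", effect),
        PlantedInteraction("Sema4d", "Plxnb1", "oligodendrocyte", "astrocyte", effect),
    ]


def scene_gene_universe(
    programs: Sequence[CellTypeProgram],
    interactions: Sequence[PlantedInteraction],
    n_genes: int,
) -> list[str]:
    """Ordered gene list: markers, then interaction genes, then filler genes."""
    named: list[str] = []
    for p in programs:
        named.extend(p.marker_genes)
    for it in interactions:
        named.extend([it.ligand_gene, it.receptor_gene])
    named = list(dict.fromkeys(named))
    if n_genes < len(named):
        raise ValueError(f"n_genes={n_genes} below the {len(named)} named genes")
    filler = [f"Gene{i:05d}" for i in range(n_genes - len(named))]
    return named + filler


def sample_counts(
    scene: ScarScene,
    programs: Sequence[CellTypeProgram],
    interactions: Sequence[PlantedInteraction] = (),
    n_genes: int = 400,
    seed: int = 0,
) -> CountMatrix:
    """Draw a UMI count matrix for a scene.

    Each spot is a sum over its constituent cells: cell types are allocated
    multinomially from the spot mixture, and each (gene, type) contributes a
    negative-binomial draw with per-cell mean ``baseline * exp(log_fold)`` for
    markers (baseline otherwise, plus any planted interaction effect) and
    size ``dispersion * n_cells``. Deterministic for fixed inputs and seed.
    """
    prog_by_type = {p.cell_type: p for p in programs}
    missing = [t for t in scene.cell_types if t not in prog_by_type]
    if missing:
        raise ConfigurationError(f"no CellTypeProgram for scene cell types: {missing}")
    marker_owner: dict[str, str] = {}
    for p in programs:
        for g in p.marker_genes:
            if g in marker_owner:
                raise ConfigurationError(f"marker gene {g} assigned to two programs")
            marker_owner[g] = p.cell_type

    genes = scene_gene_universe(programs, interactions, n_genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    types = scene.cell_types
    G, S, T = len(genes), scene.spot_mixture.shape[0], len(types)

    # Per-cell NB mean for every (gene, type).
    rate = np.empty((G, T), dtype=float)
    for j, t in enumerate(types):
        rate[:, j] = prog_by_type[t].baseline_mean
    for g, owner in marker_owner.items():
        j = types.index(owner)
        rate[gene_idx[g], j] *= math.exp(prog_by_type[owner].marker_log_fold)
    for it in interactions:
        if it.source_type not in types or it.target_type not in types:
            raise ConfigurationError(f"interaction references unknown cell type: {it}")
        rate[gene_idx[it.ligand_gene], types.index(it.source_type)] += it.effect
        rate[gene_idx[it.receptor_gene], types.index(it.target_type)] += it.effect

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(scene.time_dpi), 0xC0DE]))
    pvals = scene.spot_mixture.to_numpy()
    ncells = scene.cells_per_spot.to_numpy()
    cells_by_type = np.vstack([rng.multinomial(int(n), p) for n, p in zip(ncells, pvals)])

    counts = np.zeros((G, S), dtype=np.int64)
    for j, t in enumerate(types):
        c = cells_by_type[:, j].astype(float)  # cells of type t per spot
        active = c > 0
        if not active.any():
            continue
        mean = rate[:, j][:, None] * c[None, active]
        size = prog_by_type[t].dispersion * c[active]
        shape = np.broadcast_to(size[None, :], mean.shape)
        lam = np.zeros_like(mean)
        pos = mean > 0
        # NB(mean, size) as a gamma-Poisson mixture.
        lam[pos] = rng.gamma(shape[pos], mean[pos] / shape[pos])
        counts[:, active] += rng.poisson(lam)

    return CountMatrix(genes, list(scene.spot_mixture.index), counts)
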