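"""Readers and writers for the plain-text formats the pipeline touches.

Counts travel as Matrix Market coordinate files plus one-per-line
``features``/``barcodes`` lists (genes are matrix rows, the CellRanger
convention); spot positions as the Space Ranger ``tissue_positions`` CSV
dialect (both the headerless and the headered variant are accepted and
auto-detected); gene sets as GMT; labels and results as TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError
from .matrix import CountMatrix
from .synthetic import ScarScene, SpotLattice

logger = logging.getLogger(__name__)

POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "pixel_row", "pixel_col"]


# --------------------------------------------------------------------------
# Counts
# --------------------------------------------------------------------------

def _read_name_list(path) -> list[str]:
    names: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                # features.tsv may carry extra columns (id, symbol, type); keep the first
                names.append(line.split("\t")[0])
    return names


def read_counts(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read a gene x spot count matrix from Matrix Market + name lists."""
    try:
        X = scipy.io.mmread(str(matrix_path))
    except Exception as exc:
        raise FormatError(f"{matrix_path}: not a readable Matrix Market file ({exc})") from exc
    X = sp.csr_matrix(X)
    genes = _read_name_list(features_path)
    barcodes = _read_name_list(barcodes_path)
    if X.shape[0] != len(genes):
        raise FormatError(
            f"{matrix_path}: header declares {X.shape[0]} rows but "
            f"{features_path} lists {len(genes)} features"
        )
    if X.shape[1] != len(barcodes):
        raise FormatError(
            f"{matrix_path}: header declares {X.shape[1]} columns but "
            f"{barcodes_path} lists {len(barcodes)} barcodes"
        )
    if X.nnz:
        if np.any(X.data < 0):
            raise FormatError(f"{matrix_path}: negative count entry")
        if not np.allclose(X.data, np.round(X.data)):
            raise FormatError(f"{matrix_path}: non-integer count entry")
    return CountMatrix(genes, barcodes, X)


def write_counts(counts: CountMatrix, matrix_path, features_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(matrix_path), counts.X.tocoo(), field="integer")
    Path(features_path).write_text("".join(f"{g}\n" for g in counts.genes))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in counts.spots))


# --------------------------------------------------------------------------
# Positions
# --------------------------------------------------------------------------

def read_positions(path, in_tissue_only: bool = True) -> pd.DataFrame:
    """Read a ``tissue_positions`` CSV; header presence is auto-detected."""
    with open(path) as fh:
        first = fh.readline()
    header = 0 if first and first.split(",")[0].strip().lower() == "barcode" else None
    df = pd.read_csv(path, header=header, names=POSITION_COLUMNS if header is None else None)
    if header == 0:
        missing = [c for c in POSITION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
        df = df[POSITION_COLUMNS]
    if df.empty:
        return pd.DataFrame(columns=POSITION_COLUMNS)
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise FormatError(f"{path}: duplicate barcode {dup!r}")
    if in_tissue_only:
        df = df[df["in_tissue"] == 1]
    return df.reset_index(drop=True)


def write_positions(positions: pd.DataFrame, path, header: bool = True) -> None:
    positions.to_csv(path, index=False, header=header, columns=POSITION_COLUMNS)


def lattice_from_positions(
    positions: pd.DataFrame, pitch_um: float = 100.0, diameter_um: float = 55.0
) -> SpotLattice:
    """Rebuild a :class:`SpotLattice` from a positions table (µm in pixel cols)."""
    return SpotLattice(
        spot_ids=positions["barcode"].to_numpy(dtype=object),
        array_row=positions["array_row"].to_numpy(dtype=np.int64),
        array_col=positions["array_col"].to_numpy(dtype=np.int64),
        x_um=positions["pixel_col"].to_numpy(dtype=np.float64),
        y_um=positions["pixel_row"].to_numpy(dtype=np.float64),
        pitch_um=float(pitch_um),
        diameter_um=float(diameter_um),
    )


def lattice_positions(lattice: SpotLattice, in_tissue: int = 1) -> pd.DataFrame:
    """Positions table for a generated lattice (µm coordinates as pixels)."""
    return pd.DataFrame(
        {
            "barcode": lattice.spot_ids,
            "in_tissue": in_tissue,
            "array_row": lattice.array_row,
            "array_col": lattice.array_col,
            "pixel_row": lattice.y_um,
            "pixel_col": lattice.x_um,
        }
    )


# --------------------------------------------------------------------------
# Gene sets (GMT)
# --------------------------------------------------------------------------

def read_gene_sets(path) -> dict[str, list[str]]:
    """Read a GMT file: ``name <TAB> description <TAB> gene ...`` per line."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, _desc, *genes = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            deduped = list(dict.fromkeys(g for g in genes if g))
            if len(deduped) < sum(1 for g in genes if g):
                logger.warning("%s:%d: duplicate genes in set %r deduplicated", path, lineno, name)
            sets[name] = deduped
    return sets


def write_gene_sets(sets: Mapping[str, Sequence[str]], path, description: str = "NA") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# --------------------------------------------------------------------------
# Labels and tables
# --------------------------------------------------------------------------

def read_labels(path) -> pd.Series:
    """Read a barcode -> label TSV (two columns, headered or not)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{path}: expected two tab-separated columns")
    if df.iloc[0, 0].lower() in ("barcode", "spot_id"):
        df = df.iloc[1:]
    if df[0].duplicated().any():
        raise FormatError(f"{path}: duplicate barcode in label table")
    s = pd.Series(df[1].to_numpy(), index=pd.Index(df[0], name="barcode"), name="label")
    return s


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("label").rename_axis("barcode").to_csv(path, sep="\t", header=True)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# --------------------------------------------------------------------------
# Scene fixtures
# --------------------------------------------------------------------------

def write_scene_fixture(scene: ScarScene, counts: CountMatrix, outdir) -> dict[str, str]:
    """Write a generated scene in the exact formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.mtx",
        "features": outdir / "features.tsv",
        "barcodes": outdir / "barcodes.tsv",
        "positions": outdir / "tissue_positions.csv",
        "truth_labels": outdir / "truth_labels.tsv",
    }
    write_counts(counts, paths["matrix"], paths["features"], paths["barcodes"])
    write_positions(lattice_positions(scene.lattice), paths["positions"])
    write_labels(scene.truth_labels, paths["truth_labels"])
    return {k: str(v) for k, v in paths.items()}
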