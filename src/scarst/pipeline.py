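"""Run configuration and end-to-end pipeline orchestration.

A :class:`RunConfig` carries every tunable of the pipeline (QC threshold,
HVG count, PC count, interface width, LR threshold, permutation count,
module count, layer count, and the single seed all randomness flows from).
:func:`run_pipeline` executes simulate -> qc -> normalize -> label/score ->
geometry -> lr-test -> modules, writing one TSV artifact set per stage plus
a manifest recording the config hash and seed, so a run can be re-derived
exactly from (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexpression, geometry, preprocess, scoring, st_io, synthetic
from .errors import ConfigurationError
from .ligand_receptor import LRPair, results_to_frame, run_boundary_lr

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "normalize", "label_score", "geometry", "lr_test", "modules")


@dataclass
class RunConfig:
    """All pipeline parameters; defaults are the study's stated settings."""

    out_dir: str = "run"
    input_dir: str | None = None  # read fixture from here instead of simulating
    labels_path: str | None = None  # externally supplied domain labels
    pairs_path: str | None = None  # two-column ligand/receptor TSV
    # simulation
    time_dpi: int = 7
    n_rows: int = 40
    n_cols: int = 40
    n_genes: int = 400
    # parameters
    min_umi: int = 163
    n_hvg: int = 2000
    n_pcs: int = 30
    k_domains: int = 6
    interface_width: int = 2
    lr_threshold: float = 0.1
    n_perm: int = 1000
    k_modules: int = 18
    n_layers: int = 4
    seed: int = 0
    scar_labels: list[str] = field(
        default_factory=lambda: ["fibroblast", "macrophage", "microglia", "astrocyte"]
    )

    def validate(self) -> None:
        checks = {
            "min_umi": self.min_umi >= 0,
            "n_hvg": self.n_hvg >= 1,
            "n_pcs": self.n_pcs >= 1,
            "k_domains": self.k_domains >= 2,
            "interface_width": self.interface_width >= 1,
            "lr_threshold": 0 <= self.lr_threshold <= 1,
            "n_perm": self.n_perm >= 1,
            "k_modules": self.k_modules >= 1,
            "n_layers": self.n_layers >= 1,
            "n_rows": self.n_rows >= 1,
            "n_cols": self.n_cols >= 1,
            "time_dpi": self.time_dpi in synthetic.TIME_POINTS_DPI,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ConfigurationError(f"invalid config values: {bad}")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()


def _read_pairs(path) -> list[LRPair]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return [LRPair(l, r) for l, r in zip(df[0], df[1])]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.digest(), "seed": config.seed, "stages": {}}
    t_start = time.time()

    def record(stage: str, outputs: dict[str, str], **info) -> None:
        manifest["stages"][stage] = {
            "outputs": outputs,
            "elapsed_s": round(time.time() - t_start, 3),
            **info,
        }
        logger.info("stage %s done: %s", stage, info)

    # -- simulate ----------------------------------------------------------
    if config.input_dir is None:
        lattice = synthetic.build_lattice(config.n_rows, config.n_cols)
        scene = synthetic.make_scene(lattice, config.time_dpi, seed=config.seed)
        counts_raw = synthetic.sample_counts(
            scene,
            synthetic.default_programs(),
            synthetic.default_interactions(),
            n_genes=config.n_genes,
            seed=config.seed,
        )
        sim_paths = st_io.write_scene_fixture(scene, counts_raw, out / "simulated")
        fixture_dir = out / "simulated"
    else:
        fixture_dir = Path(config.input_dir)
        sim_paths = {"input_dir": str(fixture_dir)}
        lattice = st_io.lattice_from_positions(
            st_io.read_positions(fixture_dir / "tissue_positions.csv")
        )
    # read back through the public readers so the IO path is exercised
    counts = st_io.read_counts(
        fixture_dir / "matrix.mtx", fixture_dir / "features.tsv", fixture_dir / "barcodes.tsv"
    )
    record("simulate", sim_paths, n_genes=counts.n_genes, n_spots=counts.n_spots)

    # -- qc ----------------------------------------------------------------
    totals = counts.spot_totals()
    counts = preprocess.filter_spots(counts, config.min_umi)
    qc_path = out / "qc_spots.tsv"
    pd.DataFrame(
        {"barcode": totals.index, "total_umi": totals.to_numpy(), "kept": totals.index.isin(counts.spots)}
    ).to_csv(qc_path, sep="\t", index=False)
    record("qc", {"qc_spots": str(qc_path)}, n_spots_kept=counts.n_spots)

    # -- normalize + HVG ---------------------------------------------------
    norm = preprocess.log_normalize(counts)
    hvgs = preprocess.select_hvg(norm, min(config.n_hvg, norm.n_genes))
    hvg_path = out / "hvg.tsv"
    variances = preprocess.gene_variances(norm)
    pd.DataFrame({"gene": hvgs, "variance": variances.loc[hvgs].to_numpy()}).to_csv(
        hvg_path, sep="\t", index=False, float_format="%.10g"
    )
    record("normalize", {"hvg": str(hvg_path)}, n_hvg=len(hvgs))

    # -- label + score -----------------------------------------------------
    if config.labels_path is not None:
        labels = st_io.read_labels(config.labels_path).loc[list(norm.spots)]
    else:
        labels = preprocess.embed_and_label(
            norm, k=config.k_domains, n_components=config.n_pcs, seed=config.seed, hvgs=hvgs
        )
    score_maps = {
        ct: scoring.module_score(norm, markers, seed=config.seed)
        for ct, markers in synthetic.DEFAULT_MARKERS.items()
        if any(g in norm.genes for g in markers)
    }
    assignment = scoring.assign_cell_types(score_maps, labels)
    typed_labels = labels.map(assignment).rename("label")
    labels_path = out / "labels.tsv"
    st_io.write_labels(typed_labels, labels_path)
    assign_path = out / "cluster_cell_types.tsv"
    pd.DataFrame(sorted(assignment.items()), columns=["cluster", "cell_type"]).to_csv(
        assign_path, sep="\t", index=False
    )
    record(
        "label_score",
        {"labels": str(labels_path), "cluster_cell_types": str(assign_path)},
        n_clusters=labels.nunique(),
    )

    # -- geometry ----------------------------------------------------------
    kept = pd.Index(norm.spots)
    sub_ids = pd.Index(lattice.spot_ids)
    keep_mask = sub_ids.isin(kept)
    graph = geometry.neighbor_graph(lattice)
    layers = geometry.assign_layers(lattice, config.n_layers)
    scar_present = [l for l in config.scar_labels if (typed_labels == l).any()]
    geo_rows = {}
    if scar_present:
        cx, cy = geometry.scar_center(typed_labels, lattice, scar_present)
        r_um, r_spots = geometry.scar_radius_spots(typed_labels, lattice, scar_present)
        geo_rows = {"center_x_um": cx, "center_y_um": cy, "radius_um": r_um, "radius_spots": r_spots}
    geom_path = out / "scar_geometry.tsv"
    pd.DataFrame([geo_rows]).to_csv(geom_path, sep="\t", index=False, float_format="%.10g")
    layers_path = out / "layers.tsv"
    layers[keep_mask].rename("layer").rename_axis("barcode").to_csv(layers_path, sep="\t")
    frac_path = out / "fractions.tsv"
    fractions = geometry.celltype_fractions({config.time_dpi: typed_labels})
    st_io.write_table(fractions, frac_path)
    record(
        "geometry",
        {"scar_geometry": str(geom_path), "layers": str(layers_path), "fractions": str(frac_path)},
        **geo_rows,
    )

    # -- ligand-receptor ---------------------------------------------------
    if config.pairs_path is not None:
        pairs = _read_pairs(config.pairs_path)
    else:
        pairs = [
            LRPair(it.ligand_gene, it.receptor_gene) for it in synthetic.default_interactions()
        ]
    pairs = [p for p in pairs if p.ligand_gene in norm.genes and p.receptor_gene in norm.genes]
    lr_results = run_boundary_lr(
        norm,
        typed_labels,
        graph,
        pairs,
        width=config.interface_width,
        threshold=config.lr_threshold,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    lr_path = out / "lr_results.tsv"
    st_io.write_table(results_to_frame(lr_results), lr_path)
    record("lr_test", {"lr_results": str(lr_path)}, n_results=len(lr_results))

    # -- co-expression modules ---------------------------------------------
    corr = coexpression.gene_correlation(norm, hvgs)
    modules = coexpression.kmeans_modules(
        corr, k=min(config.k_modules, len(hvgs)), seed=config.seed
    )
    mod_path = out / "modules.tsv"
    st_io.write_table(coexpression.modules_to_frame(modules), mod_path)
    record("modules", {"modules": str(mod_path)}, n_modules=len(modules))

    config.to_yaml(out / "config.yaml")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
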