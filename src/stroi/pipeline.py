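"""End-to-end orchestration: preprocess -> segment -> ROI -> statistics.

A single flat configuration drives the whole run; every tunable the
workflow exposes appears here with its standard default (minimum 200
transcripts per spot, co-location threshold 0.01, confidence threshold
0.88, |log2 FC| cutoff 1 at adjusted p < 0.05, top 10 genes, ORA report
cutoff 0.05).  The pipeline is a pure function of (bundle, config): two
runs with the same inputs produce identical result tables.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io, preprocess, roi as roi_mod, stats
from .model import (
    BoxPrompt,
    MaskSet,
    ROISelection,
    SegmentationMode,
    SpatialDataset,
    SpotAssignment,
)
from .segmentation import get_backend, postprocess_masks, segment_boxes, segment_everything

logger = logging.getLogger("stroi")

# qualitative palette cycled by mask_id (colorblind-safe Okabe-Ito order)
PALETTE = np.array(
    [
        (230, 159, 0),
        (86, 180, 233),
        (0, 158, 115),
        (240, 228, 66),
        (0, 114, 178),
        (213, 94, 0),
        (204, 121, 167),
        (100, 100, 100),
    ],
    dtype=np.uint8,
)


@dataclass
class PipelineConfig:
    """Flat, versioned run configuration with the workflow defaults."""

    bundle: Optional[str] = None
    min_transcripts: int = 200
    min_spots_per_gene: int = 3
    target_sum: float = 1e4
    backend: str = "reference"
    k_colors: int = 4
    min_area_px: int = 64
    mode: str = "everything"
    confidence_threshold: float = 0.88
    min_proportion: float = 0.01
    proportion_def: str = "disk-coverage"
    roi1: List[int] = field(default_factory=list)
    roi2: List[int] = field(default_factory=list)
    boxes: List[Dict[str, float]] = field(default_factory=list)
    logfc_cutoff: float = 1.0
    padj_cutoff: float = 0.05
    top_n: int = 10
    ora_padj: float = 0.05
    ora_universe: str = "dataset"
    gmt: List[str] = field(default_factory=list)
    fractions: Optional[str] = None
    overlay_opacity: float = 0.5
    seed: int = 0
    outdir: Optional[str] = None
    config_version: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def resolve_bundle_paths(bundle_dir) -> Dict[str, Path]:
    """Locate the matrix, positions, scale factors and image in a bundle."""
    d = Path(bundle_dir)

    def _first(patterns, what):
        for pat in patterns:
            hits = sorted(d.glob(pat))
            if hits:
                return hits[0]
        raise FileNotFoundError(f"no {what} found in {d}")

    return {
        "matrix": _first(["matrix.mtx", "*.mtx", "*filtered*.h5", "*.h5"], "count matrix"),
        "positions": _first(["tissue_positions*.csv", "*positions*.csv"], "positions CSV"),
        "scalefactors": _first(["scalefactors*.json"], "scale-factors JSON"),
        "image": _first(
            ["tissue_image.png", "*.png", "*.tif", "*.tiff", "*.jpg", "*.jpeg"],
            "tissue image",
        ),
    }


@dataclass
class PipelineResult:
    """Everything a run produced, in memory."""

    dataset: SpatialDataset
    working_coords: np.ndarray
    crop_offset: Tuple[float, float]
    maskset: MaskSet
    selection: ROISelection
    assignment: SpotAssignment
    degs: "stats.DEGTable"
    top_genes: List[str]
    ora_tables: List["stats.ORATable"]
    proportions: Optional["stats.CellTypeProportions"]
    manifest: dict
    written: Dict[str, Path] = field(default_factory=dict)


def run_pipeline(
    config: PipelineConfig | dict,
    dataset: Optional[SpatialDataset] = None,
    gmt_libraries: Optional[Sequence[io.GeneSetLibrary]] = None,
    fractions: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    """Run the full workflow and (optionally) write the result bundle.

    ``dataset``, ``gmt_libraries`` and ``fractions`` may be passed
    in-memory (e.g. a synthetic fixture); otherwise they are read from the
    paths in the config.  Exactly one of ROI mask ids or box prompts must
    be supplied.
    """
    if isinstance(config, dict):
        config = PipelineConfig.from_dict(config)
    mode = SegmentationMode(config.mode)
    has_rois = bool(config.roi1)
    has_boxes = bool(config.boxes)
    if mode is SegmentationMode.EVERYTHING and not has_rois:
        raise ValueError("everything-mode requires roi1 mask ids in the config")
    if mode is SegmentationMode.PROMPT and not has_boxes:
        raise ValueError("prompt-mode requires box prompts in the config")

    # ---- load ----
    if dataset is None:
        if not config.bundle:
            raise ValueError("config.bundle is required when no dataset is passed")
        paths = resolve_bundle_paths(config.bundle)
        dataset = io.read_visium_bundle(
            paths["matrix"], paths["positions"], paths["scalefactors"], paths["image"]
        )
    if gmt_libraries is None:
        gmt_libraries = [io.read_gmt(p) for p in config.gmt]
    if fractions is None and config.fractions:
        fractions = io.read_fractions(config.fractions)

    manifest: dict = {"config": config.to_dict(), "stages": {}}

    # ---- preprocess ----
    ds = preprocess.filter_spots(dataset, config.min_transcripts)
    ds = preprocess.filter_genes(ds, config.min_spots_per_gene)
    ds = preprocess.lognormalize(ds, config.target_sum)
    coords = preprocess.align_coordinates(ds)
    ds, coords, offset = preprocess.crop_to_tissue(ds, coords)
    spot_diameter = ds.scale.spot_diameter_working
    manifest["stages"]["preprocess"] = {
        "spots_in": dataset.n_spots,
        "spots_kept": ds.n_spots,
        "genes_in": dataset.n_genes,
        "genes_kept": ds.n_genes,
        "crop_offset": list(offset),
    }
    logger.info(
        "preprocess: %d/%d spots, %d/%d genes kept, crop offset %s",
        ds.n_spots, dataset.n_spots, ds.n_genes, dataset.n_genes, offset,
    )

    # ---- segment ----
    backend_kwargs = (
        {"k_colors": config.k_colors, "min_area_px": config.min_area_px,
         "seed": config.seed}
        if config.backend == "reference"
        else {}
    )
    backend = get_backend(config.backend, **backend_kwargs)
    if mode is SegmentationMode.EVERYTHING:
        raw = segment_everything(backend, ds.image, config.confidence_threshold)
    else:
        boxes = [BoxPrompt(**b) for b in config.boxes]
        raw = segment_boxes(backend, ds.image, boxes)
    maskset = postprocess_masks(
        raw, ds.image.shape[:2], mode, config.confidence_threshold
    )
    in_tissue = ds.spot_table["in_tissue"].to_numpy(dtype=bool)
    if mode is SegmentationMode.EVERYTHING:
        # co-location filter applies to whole-image proposals only;
        # prompt masks answer an explicit user request
        maskset = roi_mod.filter_masks(
            maskset,
            coords[in_tissue],
            spot_diameter,
            config.min_proportion,
            config.proportion_def,
        )
    if len(maskset) == 0:
        raise RuntimeError(
            "segmentation produced no masks after filtering; lower the "
            "confidence threshold or check the image"
        )
    manifest["stages"]["segment"] = {
        "mode": mode.value,
        "backend": backend.name,
        "masks_kept": len(maskset),
        "mask_areas": [m.area_px for m in maskset],
    }
    logger.info("segment: %d masks kept (%s-mode)", len(maskset), mode.value)

    # ---- ROI ----
    if has_rois:
        selection = ROISelection(set(config.roi1), set(config.roi2))
    else:  # prompt-mode without explicit ids: every box mask forms ROI 1
        selection = ROISelection(set(maskset.ids), set())
    selection.validate_against(maskset)
    assignment = roi_mod.assign_spots(maskset, coords)
    assignment = roi_mod.build_roi(selection, assignment, in_tissue)
    n1, n2 = assignment.count("ROI1"), assignment.count("ROI2")
    manifest["stages"]["roi"] = {
        "roi1_mask_ids": sorted(selection.roi1_mask_ids),
        "roi2_mask_ids": sorted(selection.roi2_mask_ids),
        "spots_roi1": n1,
        "spots_roi2": n2,
        "spots_excluded": assignment.count("EXCLUDED"),
    }
    logger.info("roi: %d ROI1 spots vs %d ROI2 spots", n1, n2)

    # ---- statistics ----
    degs = stats.wilcoxon_deg(ds, assignment)
    degs = stats.classify_degs(degs, config.logfc_cutoff, config.padj_cutoff)
    top_genes = stats.top_degs(degs, config.top_n)
    universe = (
        ds.gene_ids
        if config.ora_universe == "dataset"
        else sorted(set().union(*(l.terms.values() for l in gmt_libraries)))
        if gmt_libraries
        else ds.gene_ids
    )
    ora_tables: List[stats.ORATable] = []
    for lib in gmt_libraries:
        for group, tag in (("up_roi1", "roi1"), ("up_roi2", "roi2")):
            genes = degs.genes_in_group(group)
            if not genes:
                continue
            t = stats.ora(genes, lib, universe, config.ora_padj)
            t.library_name = f"{lib.name}_{tag}"
            ora_tables.append(t)
    props = None
    if fractions is not None:
        props = stats.celltype_proportions(fractions, assignment, ds.barcodes)
    manifest["stages"]["stats"] = {
        "degs_up_roi1": int((degs.table["group"] == "up_roi1").sum()),
        "degs_up_roi2": int((degs.table["group"] == "up_roi2").sum()),
        "top_genes": top_genes,
        "ora_reported": {
            t.library_name: int(t.table["reported"].sum()) for t in ora_tables
        },
    }
    logger.info(
        "stats: %d up in ROI1, %d up in ROI2",
        manifest["stages"]["stats"]["degs_up_roi1"],
        manifest["stages"]["stats"]["degs_up_roi2"],
    )

    result = PipelineResult(
        dataset=ds,
        working_coords=coords,
        crop_offset=offset,
        maskset=maskset,
        selection=selection,
        assignment=assignment,
        degs=degs,
        top_genes=top_genes,
        ora_tables=ora_tables,
        proportions=props,
        manifest=manifest,
    )

    # ---- write ----
    if config.outdir:
        outdir = Path(config.outdir)
        written = io.write_results(degs, ora_tables, props, outdir, manifest)
        io.save_maskset(maskset, outdir / "masks.npz")
        written["masks"] = outdir / "masks.npz"
        labels_df = pd.DataFrame(
            {
                "barcode": ds.barcodes,
                "label": [l.value for l in assignment.labels],
                "containing_mask_ids": [
                    ";".join(map(str, sorted(s)))
                    for s in assignment.containing_mask_ids
                ],
            }
        )
        labels_df.to_csv(outdir / "labels.csv", index=False)
        written["labels"] = outdir / "labels.csv"
        overlay = render_overlay(ds.image, maskset, selection, config.overlay_opacity)
        from PIL import Image

        Image.fromarray(overlay).save(outdir / "overlay.png")
        written["overlay"] = outdir / "overlay.png"
        result.written = written
    return result


def render_overlay(
    image: np.ndarray,
    maskset: MaskSet,
    selection: Optional[ROISelection] = None,
    opacity: float = 0.5,
) -> np.ndarray:
    """Alpha-blend each mask with a palette tint; outline selected masks.

    Per channel the blend is ``(1 - opacity) * image + opacity * tint``
    with the tint cycling deterministically through the palette by
    mask_id.  Masks selected for either ROI get their one-pixel inner
    boundary painted at the same opacity with a darkened tint.
    """
    if not (0.0 <= opacity <= 1.0):
        raise ValueError("opacity must be in [0, 1]")
    out = np.asarray(image, dtype=float).copy()
    selected = (
        (selection.roi1_mask_ids | selection.roi2_mask_ids) if selection else set()
    )
    from scipy.ndimage import binary_erosion

    for mask in maskset:
        tint = PALETTE[(mask.mask_id - 1) % len(PALETTE)].astype(float)
        out[mask.raster] = (1 - opacity) * out[mask.raster] + opacity * tint
        if mask.mask_id in selected:
            boundary = mask.raster & ~binary_erosion(mask.raster)
            out[boundary] = (1 - opacity) * out[boundary] + opacity * (tint * 0.4)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
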