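"""Synthetic spatial-transcriptomics fixtures with planted ground truth.

Generates a complete miniature Visium-style bundle — a flat-color tissue
image with geometric regions, a square lattice of capture spots, negative
binomial transcript counts with planted per-region marker genes, a planted
gene-set library (one term per region plus decoys), and per-region
Dirichlet cell-type fraction profiles — so every pipeline stage can be
tested against known truth without downloading data.

Counts are negative binomial rather than Poisson because spot-level
transcript counts are overdispersed; the dispersion parameter is the NB
shape theta with ``var = mu + mu^2 / theta``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .model import ScaleFactors, SpatialDataset
from .io import GeneSetLibrary

CELL_TYPES = ["epithelial", "immune", "stromal", "endothelial", "other"]
WHITE = (255, 255, 255)


@dataclass(frozen=True)
class Region:
    """One planted tissue region: a colored rectangle or disk.

    Rectangle geometry is ``(x0, y0, x1, y1)`` (end-inclusive pixels);
    disk geometry is ``(cx, cy, radius)``.
    """

    shape: str  # "rectangle" | "disk"
    geometry: Tuple[float, ...]
    color: Tuple[int, int, int]

    def raster(self, image_shape: Tuple[int, int]) -> np.ndarray:
        h, w = image_shape
        yy, xx = np.mgrid[0:h, 0:w]
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.geometry
            return (xx >= x0) & (xx <= x1) & (yy >= y0) & (yy <= y1)
        if self.shape == "disk":
            cx, cy, r = self.geometry
            return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        raise ValueError(f"unknown region shape {self.shape!r}")

    def contains(self, x: float, y: float) -> bool:
        if self.shape == "rectangle":
            x0, y0, x1, y1 = self.geometry
            return x0 <= x <= x1 and y0 <= y <= y1
        cx, cy, r = self.geometry
        return (x - cx) ** 2 + (y - cy) ** 2 <= r**2


@dataclass
class FixtureSpec:
    """Parameters of a planted fixture.

    Defaults describe the standard two-region study condition: a 256x256
    image with two well-separated solid-color rectangles, a 12-px spot
    lattice (~400 in-tissue spots), 2000 genes with 10 four-fold
    (log2 FC = 2) markers per region over a baseline mean of 0.5
    transcripts per gene per spot with NB dispersion theta = 2.
    """

    image_shape: Tuple[int, int] = (256, 256)
    regions: List[Region] = field(default_factory=lambda: two_region_layout())
    spot_pitch: int = 12
    n_genes: int = 2000
    markers_per_region: int = 10
    marker_log2_fc: float = 2.0
    baseline_mean: float = 0.5
    dispersion: float = 2.0
    n_decoy_terms: int = 20
    decoy_term_size: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.spot_pitch < 2:
            raise ValueError("spot_pitch must be >= 2")
        if self.marker_log2_fc < 0:
            raise ValueError("marker_log2_fc must be >= 0")


def two_region_layout() -> List[Region]:
    return [
        Region("rectangle", (24, 24, 120, 232), (200, 60, 60)),
        Region("rectangle", (140, 24, 232, 232), (60, 80, 200)),
    ]


def _negative_binomial(rng: np.random.Generator, mu: np.ndarray, theta: float):
    """NB draws with mean ``mu`` and shape ``theta`` (var = mu + mu^2/theta)."""
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def make_fixture(spec: FixtureSpec) -> Tuple[SpatialDataset, dict]:
    """Build the planted dataset and its ground truth.

    Returns ``(dataset, ground_truth)`` where ground_truth holds the
    region rasters, per-spot region labels (-1 = background tissue),
    per-region marker gene lists, the planted gene-set library and the
    spot-level cell-type fraction table.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape

    # image and region rasters; overlapping regions are a spec error
    rasters = [r.raster((h, w)) for r in spec.regions]
    cover = np.zeros((h, w), dtype=int)
    for r in rasters:
        cover += r
    if np.any(cover > 1):
        raise ValueError("regions overlap")
    image = np.full((h, w, 3), WHITE, dtype=np.uint8)
    for region, raster in zip(spec.regions, rasters):
        image[raster] = region.color

    # square spot lattice; in tissue when inside a region or within one
    # pitch of one (distance transform of the region union)
    union = np.zeros((h, w), dtype=bool)
    for r in rasters:
        union |= r
    dist = ndimage.distance_transform_edt(~union)
    half = spec.spot_pitch // 2
    xs = np.arange(half, w, spec.spot_pitch)
    ys = np.arange(half, h, spec.spot_pitch)
    spot_x, spot_y, in_tissue, region_label = [], [], [], []
    for y in ys:
        for x in xs:
            spot_x.append(float(x))
            spot_y.append(float(y))
            in_tissue.append(bool(dist[y, x] <= spec.spot_pitch))
            lbl = -1
            for ridx, region in enumerate(spec.regions):
                if region.contains(x, y):
                    lbl = ridx
                    break
            region_label.append(lbl)
    n_spots = len(spot_x)
    region_label = np.array(region_label, dtype=int)
    in_tissue = np.array(in_tissue, dtype=bool)

    # planted marker genes, disjoint across regions
    n_regions = len(spec.regions)
    gene_ids = [f"GENE{i:04d}" for i in range(spec.n_genes)]
    marker_pool = rng.permutation(spec.n_genes)
    markers: List[List[int]] = [
        sorted(
            marker_pool[
                r * spec.markers_per_region : (r + 1) * spec.markers_per_region
            ].tolist()
        )
        for r in range(n_regions)
    ]

    # NB counts: baseline everywhere, markers boosted inside their region,
    # off-tissue lattice points carry faint ambient signal
    mu = np.full((n_spots, spec.n_genes), spec.baseline_mean, dtype=float)
    boost = 2.0**spec.marker_log2_fc
    for ridx, marker_idx in enumerate(markers):
        rows = np.nonzero(region_label == ridx)[0]
        for g in marker_idx:
            mu[rows, g] *= boost
    mu[~in_tissue] = spec.baseline_mean * 0.1
    counts = _negative_binomial(rng, mu, spec.dispersion).astype(np.int64)

    barcodes = [f"SPOT-{i:04d}" for i in range(n_spots)]
    spot_table = pd.DataFrame(
        {
            "barcode": barcodes,
            "in_tissue": in_tissue,
            "fullres_x": np.array(spot_x),
            "fullres_y": np.array(spot_y),
        }
    )
    ds = SpatialDataset(
        counts=counts,
        gene_ids=gene_ids,
        spot_table=spot_table,
        scale=ScaleFactors(
            hires_scalef=1.0,
            spot_diameter_fullres=max(2.0, 0.8 * spec.spot_pitch),
        ),
        image=image,
    )

    # planted gene-set library: one term per region's markers plus decoys
    # drawn from non-marker genes
    terms: Dict[str, set] = {}
    for ridx, marker_idx in enumerate(markers):
        terms[f"REGION{ridx}_MARKERS"] = {gene_ids[g] for g in marker_idx}
    all_markers = {g for m in markers for g in m}
    non_markers = np.array(sorted(set(range(spec.n_genes)) - all_markers))
    for d in range(spec.n_decoy_terms):
        pick = rng.choice(non_markers, size=spec.decoy_term_size, replace=False)
        terms[f"DECOY{d:02d}"] = {gene_ids[g] for g in pick}
    library = GeneSetLibrary(name="planted", terms=terms)

    # per-region Dirichlet cell-type profiles; spots sample around their
    # region's profile, background tissue around its own
    profiles = rng.dirichlet(np.ones(len(CELL_TYPES)), size=n_regions + 1)
    frac = np.zeros((n_spots, len(CELL_TYPES)))
    for i in range(n_spots):
        prof = profiles[region_label[i]] if region_label[i] >= 0 else profiles[-1]
        frac[i] = rng.dirichlet(prof * 50 + 1e-3)
    fractions = pd.DataFrame(frac, index=barcodes, columns=CELL_TYPES)

    ground_truth = {
        "region_rasters": rasters,
        "region_labels": region_label,
        "markers": [[gene_ids[g] for g in m] for m in markers],
        "library": library,
        "fractions": fractions,
        "region_profiles": profiles,
    }
    return ds, ground_truth


def write_fixture_bundle(
    ds: SpatialDataset,
    ground_truth: dict,
    outdir,
    positions_dialect: str = "headered",
) -> Dict[str, Path]:
    """Write the fixture as an on-disk Visium-style bundle.

    Produces matrix.mtx + features.tsv + barcodes.tsv, a tissue_positions
    CSV (headered or headerless dialect), scalefactors_json.json, the
    tissue image PNG, the planted GMT, the fraction CSV and a
    ground_truth.json with region geometry and marker lists.
    """
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    mat = csr_matrix(np.asarray(ds.counts).T)  # genes x spots, 10x layout
    paths["matrix"] = outdir / "matrix.mtx"
    mmwrite(paths["matrix"], mat, field="integer")
    paths["features"] = outdir / "features.tsv"
    with open(paths["features"], "w") as fh:
        for g in ds.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    paths["barcodes"] = outdir / "barcodes.tsv"
    with open(paths["barcodes"], "w") as fh:
        fh.write("\n".join(ds.barcodes) + "\n")

    pos = pd.DataFrame(
        {
            "barcode": ds.spot_table["barcode"],
            "in_tissue": ds.spot_table["in_tissue"].astype(int),
            "array_row": 0,
            "array_col": 0,
            "pxl_row_in_fullres": ds.spot_table["fullres_y"],
            "pxl_col_in_fullres": ds.spot_table["fullres_x"],
        }
    )
    paths["positions"] = outdir / "tissue_positions.csv"
    pos.to_csv(
        paths["positions"], index=False, header=positions_dialect == "headered"
    )

    paths["scalefactors"] = outdir / "scalefactors_json.json"
    with open(paths["scalefactors"], "w") as fh:
        json.dump(
            {
                "tissue_hires_scalef": ds.scale.hires_scalef,
                "spot_diameter_fullres": ds.scale.spot_diameter_fullres,
            },
            fh,
        )

    paths["image"] = outdir / "tissue_image.png"
    Image.fromarray(ds.image).save(paths["image"])

    library: GeneSetLibrary = ground_truth["library"]
    paths["gmt"] = outdir / "planted.gmt"
    with open(paths["gmt"], "w") as fh:
        for term, genes in library.terms.items():
            fh.write("\t".join([term, "planted"] + sorted(genes)) + "\n")

    paths["fractions"] = outdir / "fractions.csv"
    ground_truth["fractions"].to_csv(paths["fractions"])

    paths["ground_truth"] = outdir / "ground_truth.json"
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "markers": ground_truth["markers"],
                "region_labels": ground_truth["region_labels"].tolist(),
            },
            fh,
        )
    return paths
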