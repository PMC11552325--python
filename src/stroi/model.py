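"""Core domain types for segmentation-guided spatial-transcriptomics analysis.

The central container is :class:`SpatialDataset`, which holds the raw
gene-by-spot count matrix, the per-spot position table, the platform scale
factors and the tissue image.  Every pipeline stage consumes and returns
these types; nothing downstream touches raw files.

Conventions
-----------
* Pixel coordinates are 0-based with ``(x, y) = (column, row)``.
* Spot positions are stored in full-resolution pixels and converted to
  working-image pixels by multiplying with the hires scale factor.
* Rasterizing a floating-point position uses round-half-up
  (``floor(v + 0.5)``) so the convention is explicit and testable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd


def round_half_up(values) -> np.ndarray:
    """Round to nearest integer, halves away from floor ties upward.

    numpy's ``round`` rounds half to even; image indexing here needs the
    deterministic half-up rule, i.e. ``floor(v + 0.5)``.
    """
    return np.floor(np.asarray(values, dtype=float) + 0.5).astype(np.int64)


@dataclass(frozen=True)
class ScaleFactors:
    """Visium-style scale metadata.

    Attributes
    ----------
    hires_scalef:
        Multiplier taking full-resolution pixel coordinates to the working
        (hires) image.  Strictly positive.
    spot_diameter_fullres:
        Capture-spot diameter in full-resolution pixels.  Strictly positive.
    """

    hires_scalef: float
    spot_diameter_fullres: float

    def __post_init__(self):
        if not (self.hires_scalef > 0 and np.isfinite(self.hires_scalef)):
            raise ValueError(f"hires_scalef must be > 0, got {self.hires_scalef}")
        if not (self.spot_diameter_fullres > 0 and np.isfinite(self.spot_diameter_fullres)):
            raise ValueError(
                f"spot_diameter_fullres must be > 0, got {self.spot_diameter_fullres}"
            )

    @property
    def spot_diameter_working(self) -> float:
        """Spot diameter in working-image pixels."""
        return self.spot_diameter_fullres * self.hires_scalef


@dataclass
class SpatialDataset:
    """A spot-based spatial-transcriptomics bundle.

    Attributes
    ----------
    counts:
        ``(n_spots, n_genes)`` non-negative integer matrix of raw transcript
        counts (dense numpy array).
    gene_ids:
        Ordered, unique gene symbols, one per counts column.
    spot_table:
        DataFrame with columns ``barcode`` (str), ``in_tissue`` (bool),
        ``fullres_x``, ``fullres_y`` (full-resolution pixels), aligned row
        for row with ``counts``.
    scale:
        :class:`ScaleFactors`.
    image:
        ``(H, W, 3)`` uint8 RGB raster.
    normalized:
        Optional ``(n_spots, n_genes)`` float matrix, present after
        log-normalization; ``counts`` is retained unchanged alongside it.
    """

    counts: np.ndarray
    gene_ids: List[str]
    spot_table: pd.DataFrame
    scale: ScaleFactors
    image: np.ndarray
    normalized: Optional[np.ndarray] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (spots x genes)")
        if self.counts.shape[0] != len(self.spot_table):
            raise ValueError(
                f"counts has {self.counts.shape[0]} rows but spot_table has "
                f"{len(self.spot_table)}"
            )
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValueError("counts column count must match gene_ids length")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        required = {"barcode", "in_tissue", "fullres_x", "fullres_y"}
        missing = required - set(self.spot_table.columns)
        if missing:
            raise ValueError(f"spot_table missing columns: {sorted(missing)}")
        xy = self.spot_table[["fullres_x", "fullres_y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)) or np.any(xy < 0):
            raise ValueError("fullres coordinates must be finite and >= 0")
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be H x W x 3 RGB")
        if self.normalized is not None:
            self.normalized = np.asarray(self.normalized, dtype=float)
            if self.normalized.shape != self.counts.shape:
                raise ValueError("normalized must have the same shape as counts")

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def barcodes(self) -> List[str]:
        return self.spot_table["barcode"].tolist()

    def copy(self) -> "SpatialDataset":
        return SpatialDataset(
            counts=self.counts.copy(),
            gene_ids=list(self.gene_ids),
            spot_table=self.spot_table.copy().reset_index(drop=True),
            scale=self.scale,
            image=self.image.copy(),
            normalized=None if self.normalized is None else self.normalized.copy(),
        )

    def subset_spots(self, mask: np.ndarray) -> "SpatialDataset":
        """Row-consistent subset of spots by boolean mask or index array."""
        mask = np.asarray(mask)
        return SpatialDataset(
            counts=self.counts[mask],
            gene_ids=list(self.gene_ids),
            spot_table=self.spot_table.iloc[mask].reset_index(drop=True)
            if mask.dtype != bool
            else self.spot_table.loc[mask].reset_index(drop=True),
            scale=self.scale,
            image=self.image,
            normalized=None if self.normalized is None else self.normalized[mask],
        )

    def subset_genes(self, mask: np.ndarray) -> "SpatialDataset":
        mask = np.asarray(mask)
        gene_ids = [g for g, keep in zip(self.gene_ids, mask) if keep] \
            if mask.dtype == bool else [self.gene_ids[i] for i in mask]
        return SpatialDataset(
            counts=self.counts[:, mask],
            gene_ids=gene_ids,
            spot_table=self.spot_table.copy().reset_index(drop=True),
            scale=self.scale,
            image=self.image,
            normalized=None if self.normalized is None else self.normalized[:, mask],
        )


@dataclass
class SegmentMask:
    """One boolean segmentation mask with its confidence score.

    ``mask_id`` is the 1-based rank by descending area assigned by
    :func:`stroi.segmentation.postprocess_masks`; raw backend output uses
    ``mask_id=0`` until ranked.
    """

    mask_id: int
    raster: np.ndarray
    score: float
    area_px: int = -1

    def __post_init__(self):
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.ndim != 2:
            raise ValueError("mask raster must be 2-D")
        true_count = int(self.raster.sum())
        if self.area_px == -1:
            self.area_px = true_count
        if self.area_px != true_count:
            raise ValueError(f"area_px {self.area_px} != true pixel count {true_count}")
        if self.area_px <= 0:
            raise ValueError("mask must contain at least one true pixel")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")


class SegmentationMode(str, Enum):
    EVERYTHING = "everything"
    PROMPT = "prompt"


@dataclass
class MaskSet:
    """Ordered collection of masks sharing one image shape.

    Masks are sorted by area, largest first, and ``mask_id`` equals the
    1-based position in that order (mask 1 is the largest).
    """

    masks: List[SegmentMask]
    mode: SegmentationMode
    image_shape: Tuple[int, int]
    threshold_used: float = 0.0

    def __post_init__(self):
        self.mode = SegmentationMode(self.mode)
        for m in self.masks:
            if m.raster.shape != tuple(self.image_shape):
                raise ValueError("all mask rasters must share image_shape")
        areas = [m.area_px for m in self.masks]
        if any(a < b for a, b in zip(areas, areas[1:])):
            raise ValueError("masks must be sorted by area, non-increasing")
        for pos, m in enumerate(self.masks, start=1):
            if m.mask_id != pos:
                raise ValueError("mask_id must equal 1-based position in order")

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self):
        return iter(self.masks)

    def get(self, mask_id: int) -> SegmentMask:
        for m in self.masks:
            if m.mask_id == mask_id:
                return m
        raise KeyError(f"no mask with id {mask_id}")

    @property
    def ids(self) -> List[int]:
        return [m.mask_id for m in self.masks]


@dataclass(frozen=True)
class BoxPrompt:
    """Axis-aligned rectangle prompt in working-image pixels."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self):
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(
                f"box must satisfy x0 < x1 and y0 < y1, got {self}"
            )

    def intersects(self, image_shape: Tuple[int, int]) -> bool:
        h, w = image_shape[:2]
        return self.x1 > 0 and self.y1 > 0 and self.x0 < w and self.y0 < h

    def clip(self, image_shape: Tuple[int, int]) -> Tuple[int, int, int, int]:
        """Integer pixel window (x0, y0, x1, y1), end-exclusive, clipped."""
        h, w = image_shape[:2]
        x0 = max(0, int(np.floor(self.x0)))
        y0 = max(0, int(np.floor(self.y0)))
        x1 = min(w, int(np.ceil(self.x1)))
        y1 = min(h, int(np.ceil(self.y1)))
        return x0, y0, x1, y1


@dataclass
class ROISelection:
    """Which mask ids make up ROI 1 and ROI 2.

    ROI 2 may be empty, which downstream means a one-versus-others
    contrast: every in-tissue spot outside ROI 1 becomes the comparison
    group.
    """

    roi1_mask_ids: Set[int]
    roi2_mask_ids: Set[int] = field(default_factory=set)

    def __post_init__(self):
        self.roi1_mask_ids = set(self.roi1_mask_ids)
        self.roi2_mask_ids = set(self.roi2_mask_ids)
        overlap = self.roi1_mask_ids & self.roi2_mask_ids
        if overlap:
            raise ValueError(f"mask ids in both ROIs: {sorted(overlap)}")

    def validate_against(self, maskset: MaskSet) -> None:
        known = set(maskset.ids)
        unknown = (self.roi1_mask_ids | self.roi2_mask_ids) - known
        if unknown:
            raise ValueError(f"unknown mask ids: {sorted(unknown)}")


class SpotLabel(str, Enum):
    ROI1 = "ROI1"
    ROI2 = "ROI2"
    OTHER = "OTHER"
    EXCLUDED = "EXCLUDED"


@dataclass
class SpotAssignment:
    """Per-spot ROI label and containing mask ids.

    ``labels`` aligns with the dataset's spot order.  ``EXCLUDED`` marks
    spots claimed by masks of both ROIs; they are dropped from the DEG
    contrast rather than arbitrarily assigned.
    """

    labels: List[SpotLabel]
    containing_mask_ids: List[Set[int]]

    def __post_init__(self):
        self.labels = [SpotLabel(l) for l in self.labels]
        if len(self.labels) != len(self.containing_mask_ids):
            raise ValueError("labels and containing_mask_ids must align")

    def indices(self, label: SpotLabel) -> np.ndarray:
        label = SpotLabel(label)
        return np.array([i for i, l in enumerate(self.labels) if l is label], dtype=int)

    def count(self, label: SpotLabel) -> int:
        return len(self.indices(label))


@dataclass
class GeneSetLibrary:
    """Named collection of gene sets (e.g. one GMT file).

    Gene symbols are stored uppercased so matching against expression data
    is case-insensitive at query time.
    """

    name: str
    terms: Dict[str, Set[str]]

    def __post_init__(self):
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            self.terms[term] = {g.upper() for g in genes}

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class AffineTransform:
    """2x3 affine map from source (x, y) to image pixels.

    ``[[a, b, tx], [c, d, ty]]`` maps ``(x, y) -> (a x + b y + tx,
    c x + d y + ty)``.  The linear part must be non-singular.
    """

    matrix: Tuple[Tuple[float, float, float], Tuple[float, float, float]]

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (2, 3):
            raise ValueError("affine matrix must be 2x3")
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        if abs(det) <= 1e-12:
            raise ValueError(f"linear part is singular (|det| = {abs(det):.3g})")
        object.__setattr__(self, "matrix", tuple(map(tuple, m.tolist())))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    def inverse(self) -> "AffineTransform":
        m = self.array
        lin = m[:, :2]
        t = m[:, 2]
        lin_inv = np.linalg.inv(lin)
        t_inv = -lin_inv @ t
        return AffineTransform(tuple(map(tuple, np.hstack([lin_inv, t_inv[:, None]]))))


# Result tables -------------------------------------------------------------

DEG_COLUMNS = ["gene", "log_fc", "p_value", "p_adj", "mean_roi1", "mean_roi2", "group"]
ORA_COLUMNS = ["term", "k", "K", "n", "N", "p_value", "p_adj", "reported"]


@dataclass
class DEGTable:
    """Per-gene differential-expression results between ROI 1 and ROI 2.

    ``log_fc`` is in log2 units, positive meaning up-regulated in ROI 1.
    ``group`` is one of ``up_roi1`` / ``up_roi2`` / ``ns`` after cutoff
    classification (``ns`` before).
    """

    table: pd.DataFrame
    logfc_cutoff: Optional[float] = None
    padj_cutoff: Optional[float] = None

    def __post_init__(self):
        missing = set(DEG_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"DEG table missing columns: {sorted(missing)}")
        t = self.table
        if len(t) and np.any(t["p_adj"].to_numpy() < t["p_value"].to_numpy() - 1e-12):
            raise ValueError("p_adj must be >= p_value elementwise")

    def __len__(self) -> int:
        return len(self.table)

    def genes_in_group(self, group: str) -> List[str]:
        return self.table.loc[self.table["group"] == group, "gene"].tolist()


@dataclass
class ORATable:
    """Per-term over-representation results.

    ``k`` overlap, ``K`` term size in universe, ``n`` query size in
    universe, ``N`` universe size; upper-tail hypergeometric p and BH
    adjustment.  ``reported`` flags rows passing the display cutoff; all
    rows are retained.
    """

    table: pd.DataFrame
    library_name: str = ""

    def __post_init__(self):
        missing = set(ORA_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"ORA table missing columns: {sorted(missing)}")
        t = self.table
        if len(t):
            if np.any(t["k"] > np.minimum(t["K"], t["n"])):
                raise ValueError("k must be <= min(K, n)")
            if np.any(t["N"] < t["K"]) or np.any(t["N"] < t["n"]):
                raise ValueError("N must be >= K and >= n")
            p = t["p_value"].to_numpy()
            if np.any(p <= 0) or np.any(p > 1):
                raise ValueError("p_value must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def reported(self) -> pd.DataFrame:
        return self.table.loc[self.table["reported"]]


@dataclass
class CellTypeProportions:
    """Spot-level cell-type fractions plus per-ROI mean profiles.

    ``fractions`` is spots x cell types; ``roi_means`` holds one mean
    fraction vector per ROI label plus the spot count that produced it.
    """

    fractions: pd.DataFrame
    roi_means: pd.DataFrame
    roi_counts: Dict[str, int]

    def __post_init__(self):
        vals = self.fractions.to_numpy(dtype=float)
        if vals.size and (np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9)):
            raise ValueError("fractions must lie in [0, 1]")
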