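"""Spot/gene filtering, normalization and image-spot coordinate alignment.

The preprocessing contract mirrors the standard Visium workflow: drop
spots outside the tissue or with fewer than 200 transcripts, log-normalize
each spot to a common total, scale full-resolution spot positions into the
working image with the hires scale factor, and crop the image tight around
the tissue so segmentation sees tissue rather than fiducials or slide
background.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Tuple

import numpy as np

from .model import AffineTransform, ScaleFactors, SpatialDataset


def filter_spots(ds: SpatialDataset, min_transcripts: int = 200) -> SpatialDataset:
    """Remove not-in-tissue spots and spots with too few transcripts.

    A spot is kept when it is in tissue and its total transcript count is
    at least ``min_transcripts`` (only strictly fewer are excluded, so a
    spot with exactly the threshold survives).
    """
    totals = np.asarray(ds.counts).sum(axis=1)
    in_tissue = ds.spot_table["in_tissue"].to_numpy(dtype=bool)
    keep = in_tissue & (totals >= min_transcripts)
    if not keep.any():
        max_total = int(totals[in_tissue].max()) if in_tissue.any() else 0
        raise ValueError(
            f"no spots pass min_transcripts={min_transcripts} "
            f"(max in-tissue total observed: {max_total})"
        )
    return ds.subset_spots(keep)


def filter_genes(ds: SpatialDataset, min_spots: int = 3) -> SpatialDataset:
    """Drop genes detected (count > 0) in fewer than ``min_spots`` spots."""
    detected = (np.asarray(ds.counts) > 0).sum(axis=0)
    keep = detected >= min_spots
    if not keep.any():
        raise ValueError(f"no genes detected in >= {min_spots} spots")
    return ds.subset_genes(keep)


def lognormalize(ds: SpatialDataset, target_sum: float = 1e4) -> SpatialDataset:
    """Per-spot library-size normalization followed by log1p.

    ``normalized[i, j] = ln(1 + counts[i, j] * target_sum / total_i)``.
    Raw counts are retained unchanged.  Spots with zero total (impossible
    after :func:`filter_spots` with threshold >= 1) are an error.
    """
    counts = np.asarray(ds.counts, dtype=float)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.sum(totals <= 0))
        raise ValueError(f"{bad} spot(s) with zero total count; filter spots first")
    out = ds.copy()
    out.normalized = np.log1p(counts * (target_sum / totals)[:, None])
    return out


def align_coordinates(ds: SpatialDataset) -> np.ndarray:
    """Working-image spot coordinates: full-res (x, y) times hires_scalef.

    Returns an ``(n_spots, 2)`` float array of (x, y).  The matching
    working spot diameter is ``ds.scale.spot_diameter_working``.
    """
    xy = ds.spot_table[["fullres_x", "fullres_y"]].to_numpy(dtype=float)
    return xy * ds.scale.hires_scalef


def crop_to_tissue(
    ds: SpatialDataset,
    working_coords: Optional[np.ndarray] = None,
    pad: Optional[float] = None,
) -> Tuple[SpatialDataset, np.ndarray, Tuple[float, float]]:
    """Crop the image to the in-tissue bounding box plus padding.

    Padding defaults to one working spot diameter.  The window is the
    bounding box of in-tissue working coordinates expanded by ``pad``,
    with inclusive integer bounds ``floor(min - pad) .. ceil(max + pad)``,
    clipped to the image; degenerate windows are expanded to at least
    2 x 2 pixels.  Returns ``(dataset with cropped image, shifted
    working coords, (offset_x, offset_y))``; counts are untouched.
    """
    if working_coords is None:
        working_coords = align_coordinates(ds)
    working_coords = np.asarray(working_coords, dtype=float)
    in_tissue = ds.spot_table["in_tissue"].to_numpy(dtype=bool)
    if not in_tissue.any():
        raise ValueError("no in-tissue spots to crop around")
    if pad is None:
        pad = ds.scale.spot_diameter_working

    h, w = ds.image.shape[:2]
    tissue = working_coords[in_tissue]
    x0 = max(0, math.floor(tissue[:, 0].min() - pad))
    x1 = min(w - 1, math.ceil(tissue[:, 0].max() + pad))
    y0 = max(0, math.floor(tissue[:, 1].min() - pad))
    y1 = min(h - 1, math.ceil(tissue[:, 1].max() + pad))
    # degenerate windows still need raster area downstream
    if x1 <= x0:
        x1 = min(w - 1, x0 + 1) if x0 + 1 <= w - 1 else x1
        x0 = max(0, x1 - 1)
    if y1 <= y0:
        y1 = min(h - 1, y0 + 1) if y0 + 1 <= h - 1 else y1
        y0 = max(0, y1 - 1)

    out = ds.copy()
    out.image = ds.image[y0 : y1 + 1, x0 : x1 + 1].copy()
    shifted = working_coords - np.array([x0, y0], dtype=float)

    ch, cw = out.image.shape[:2]
    oob = in_tissue & (
        (shifted[:, 0] < 0)
        | (shifted[:, 0] > cw - 1)
        | (shifted[:, 1] < 0)
        | (shifted[:, 1] > ch - 1)
    )
    if oob.any():
        bad = ds.spot_table.loc[oob, "barcode"].tolist()
        warnings.warn(
            f"{len(bad)} spot(s) fall outside the cropped image and will be "
            f"labeled OTHER downstream: {bad[:5]}{'...' if len(bad) > 5 else ''}",
            stacklevel=2,
        )
    return out, shifted, (float(x0), float(y0))


def apply_affine(
    coords: np.ndarray,
    t: AffineTransform,
    image_shape: Tuple[int, int],
) -> Tuple[np.ndarray, np.ndarray]:
    """Map source (x, y) coordinates into image pixels with a 2x3 affine.

    Returns ``(transformed coords, in_bounds flags)``.  Points landing
    outside the image are flagged, not dropped, so callers can label them
    rather than silently losing spots.
    """
    coords = np.asarray(coords, dtype=float)
    m = t.array
    xy = coords @ m[:, :2].T + m[:, 2]
    h, w = image_shape[:2]
    in_bounds = (
        (xy[:, 0] >= 0) & (xy[:, 0] <= w - 1) & (xy[:, 1] >= 0) & (xy[:, 1] <= h - 1)
    )
    return xy, in_bounds
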