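"""Spot-mask geometry: assignment, co-location filtering, ROI building.

Everything-mode segmenters propose masks over the whole image, including
regions with no capture spots; those are useless for expression analysis.
The co-location filter measures, per mask, the fraction of mask pixels
covered by the union of spot disks and removes masks below a small
threshold (default 0.01), so only masks actually sampled by the assay
survive.  ROI construction then turns selected mask ids into per-spot
labels, with an empty ROI 2 meaning one-versus-others.
"""

from __future__ import annotations

import warnings
from typing import List, Optional, Sequence, Set, Tuple

import numpy as np

from .model import (
    MaskSet,
    ROISelection,
    SegmentMask,
    SpotAssignment,
    SpotLabel,
    round_half_up,
)
from .segmentation import postprocess_masks


def assign_spots(maskset: MaskSet, working_coords: np.ndarray) -> SpotAssignment:
    """Containment-only assignment: which masks hold each spot center.

    A spot belongs to every mask whose raster is true at the spot's
    rounded pixel; multiple membership is allowed (segmenters overlap).
    Spots rounding outside the image get an empty membership set.
    """
    coords = np.asarray(working_coords, dtype=float)
    h, w = maskset.image_shape
    cols = round_half_up(coords[:, 0])
    rows = round_half_up(coords[:, 1])
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    memberships: List[Set[int]] = [set() for _ in range(len(coords))]
    for mask in maskset:
        hit = np.zeros(len(coords), dtype=bool)
        hit[inside] = mask.raster[rows[inside], cols[inside]]
        for i in np.nonzero(hit)[0]:
            memberships[i].add(mask.mask_id)
    return SpotAssignment(
        labels=[SpotLabel.OTHER] * len(coords), containing_mask_ids=memberships
    )


def rasterize_spot_disks(
    working_coords: np.ndarray,
    spot_diameter_px: float,
    image_shape: Tuple[int, int],
) -> np.ndarray:
    """Boolean union of spot disks on an image-shaped canvas.

    A pixel (row, col) is covered by a spot at (x, y) when its center lies
    within ``spot_diameter_px / 2`` of the spot center.
    """
    if spot_diameter_px <= 0:
        raise ValueError("spot_diameter_px must be > 0")
    h, w = image_shape
    canvas = np.zeros((h, w), dtype=bool)
    r = spot_diameter_px / 2.0
    r2 = r * r
    for x, y in np.asarray(working_coords, dtype=float):
        r0 = max(0, int(np.floor(y - r)))
        r1 = min(h - 1, int(np.ceil(y + r)))
        c0 = max(0, int(np.floor(x - r)))
        c1 = min(w - 1, int(np.ceil(x + r)))
        if r1 < r0 or c1 < c0:
            continue
        rows = np.arange(r0, r1 + 1)
        cols = np.arange(c0, c1 + 1)
        dy2 = (rows - y) ** 2
        dx2 = (cols - x) ** 2
        canvas[r0 : r1 + 1, c0 : c1 + 1] |= dy2[:, None] + dx2[None, :] <= r2
    return canvas


def colocation_proportion(
    mask: SegmentMask,
    working_coords: np.ndarray,
    spot_diameter_px: float,
    spot_union: Optional[np.ndarray] = None,
) -> float:
    """Fraction of mask pixels covered by the union of spot disks.

    ``spot_union`` lets callers precompute :func:`rasterize_spot_disks`
    once when scoring many masks against the same spots.
    """
    if spot_union is None:
        spot_union = rasterize_spot_disks(
            working_coords, spot_diameter_px, mask.raster.shape
        )
    covered = int(np.count_nonzero(mask.raster & spot_union))
    return covered / mask.area_px


def _spots_in_mask_proportion(
    mask: SegmentMask, working_coords: np.ndarray
) -> float:
    """Alternative proportion: fraction of spots whose center lies in the mask."""
    coords = np.asarray(working_coords, dtype=float)
    if len(coords) == 0:
        return 0.0
    h, w = mask.raster.shape
    cols = round_half_up(coords[:, 0])
    rows = round_half_up(coords[:, 1])
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    hit = np.zeros(len(coords), dtype=bool)
    hit[inside] = mask.raster[rows[inside], cols[inside]]
    return float(hit.mean())


def filter_masks(
    maskset: MaskSet,
    working_coords: np.ndarray,
    spot_diameter_px: float,
    min_proportion: float = 0.01,
    proportion_def: str = "disk-coverage",
) -> MaskSet:
    """Drop masks insufficiently co-located with spots; re-rank survivors.

    The primary definition scores each mask by the fraction of its pixels
    covered by spot disks (scale-free in mask size); ``spots-in-mask``
    instead scores by the fraction of all given spots falling inside the
    mask.  Masks scoring below ``min_proportion`` are removed and the
    survivors re-ranked by area with fresh 1-based ids.
    """
    if proportion_def not in {"disk-coverage", "spots-in-mask"}:
        raise ValueError(f"unknown proportion_def {proportion_def!r}")
    if proportion_def == "disk-coverage":
        union = rasterize_spot_disks(
            working_coords, spot_diameter_px, maskset.image_shape
        )
        scores = [
            colocation_proportion(m, working_coords, spot_diameter_px, spot_union=union)
            for m in maskset
        ]
    else:
        scores = [_spots_in_mask_proportion(m, working_coords) for m in maskset]
    survivors = [m for m, s in zip(maskset.masks, scores) if s >= min_proportion]
    if not survivors and len(maskset):
        warnings.warn(
            f"all {len(maskset)} mask(s) removed by co-location filter "
            f"(threshold {min_proportion})",
            stacklevel=2,
        )
    return postprocess_masks(
        survivors, maskset.image_shape, maskset.mode, maskset.threshold_used
    )


def select_mask_at(
    maskset: MaskSet,
    point: Tuple[float, float],
    current: ROISelection,
    target_roi: int,
) -> Tuple[ROISelection, Optional[str]]:
    """Toggle the smallest mask under ``point`` in the target ROI.

    Among all masks containing the point the smallest-area one is chosen,
    so nested fine structures stay clickable under their parent.  Clicking
    a selected mask deselects it; selecting into one ROI removes the mask
    from the other.  Returns the new selection and an optional notice.
    """
    if target_roi not in (1, 2):
        raise ValueError("target_roi must be 1 or 2")
    x, y = point
    h, w = maskset.image_shape
    col, row = int(round_half_up(x)), int(round_half_up(y))
    if not (0 <= row < h and 0 <= col < w):
        raise ValueError(f"point {point} outside image {maskset.image_shape}")
    hits = [m for m in maskset if m.raster[row, col]]
    if not hits:
        return current, "no mask at this point; selection unchanged"
    chosen = min(hits, key=lambda m: m.area_px).mask_id

    roi1 = set(current.roi1_mask_ids)
    roi2 = set(current.roi2_mask_ids)
    target, other = (roi1, roi2) if target_roi == 1 else (roi2, roi1)
    if chosen in target:
        target.discard(chosen)
    else:
        target.add(chosen)
        other.discard(chosen)
    return ROISelection(roi1_mask_ids=roi1, roi2_mask_ids=roi2), None


def build_roi(
    selection: ROISelection,
    assignment: SpotAssignment,
    in_tissue_flags: Sequence[bool],
) -> SpotAssignment:
    """Label spots ROI1/ROI2/OTHER/EXCLUDED from the mask selection.

    A spot is ROI1 if any containing mask is selected for ROI 1, ROI2
    likewise; with an empty ROI 2 every remaining in-tissue spot becomes
    the comparison group (one-versus-others).  Spots claimed by both ROIs
    are EXCLUDED; not-in-tissue spots are always OTHER.
    """
    if not selection.roi1_mask_ids:
        raise ValueError("ROI 1 must contain at least one mask")
    in_tissue = np.asarray(in_tissue_flags, dtype=bool)
    if len(in_tissue) != len(assignment.labels):
        raise ValueError("in_tissue_flags must align with assignment")

    one_vs_others = not selection.roi2_mask_ids
    labels: List[SpotLabel] = []
    n_excluded = 0
    for i, members in enumerate(assignment.containing_mask_ids):
        if not in_tissue[i]:
            labels.append(SpotLabel.OTHER)
            continue
        hit1 = bool(members & selection.roi1_mask_ids)
        hit2 = bool(members & selection.roi2_mask_ids)
        if hit1 and hit2:
            labels.append(SpotLabel.EXCLUDED)
            n_excluded += 1
        elif hit1:
            labels.append(SpotLabel.ROI1)
        elif hit2 or one_vs_others:
            labels.append(SpotLabel.ROI2)
        else:
            labels.append(SpotLabel.OTHER)

    n1 = labels.count(SpotLabel.ROI1)
    n2 = labels.count(SpotLabel.ROI2)
    if n1 == 0:
        raise ValueError("ROI 1 contains no spots; select a mask containing spots")
    if n2 == 0:
        raise ValueError(
            "ROI 2 contains no spots; select a mask containing spots "
            "or leave ROI 2 empty for one-versus-others"
        )
    if n_excluded:
        warnings.warn(
            f"{n_excluded} spot(s) lie in masks of both ROIs and are excluded "
            "from the contrast",
            stacklevel=2,
        )
    return SpotAssignment(
        labels=labels, containing_mask_ids=assignment.containing_mask_ids
    )
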