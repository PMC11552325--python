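"""Pluggable segmentation backends and mask post-processing.

A backend is anything implementing the :class:`SegmenterBackend` protocol:
an ``everything`` mode proposing masks for the whole image, each with a
confidence score in [0, 1] (for SAM this is the predicted-IoU score), and
a ``boxes`` mode returning exactly one mask per rectangle prompt.  The
heavy promptable model is therefore optional; the built-in
:class:`ReferenceSegmenter` is a deterministic color-clustering segmenter
that exercises every downstream contract without model weights.
"""

from __future__ import annotations

from typing import Callable, Dict, List, Protocol, Sequence, Tuple, runtime_checkable

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .model import BoxPrompt, MaskSet, SegmentMask, SegmentationMode

# 8-connectivity structuring element for blob extraction
_STRUCT8 = np.ones((3, 3), dtype=int)


@runtime_checkable
class SegmenterBackend(Protocol):
    """Contract every segmentation backend satisfies."""

    name: str
    capabilities: frozenset

    def everything(self, image: np.ndarray, threshold: float) -> List[SegmentMask]:
        """Propose masks for the whole image; scores in [0, 1]."""
        ...

    def from_boxes(
        self, image: np.ndarray, boxes: Sequence[BoxPrompt]
    ) -> List[SegmentMask]:
        """One mask per box, in box order."""
        ...


def segment_everything(
    backend: SegmenterBackend, image: np.ndarray, confidence_threshold: float
) -> List[SegmentMask]:
    """Whole-image mask proposal filtered by confidence.

    Only masks scoring at least ``confidence_threshold`` are returned, so
    raising the threshold never increases the mask count for a fixed
    backend and image.
    """
    if not (0.0 <= confidence_threshold <= 1.0):
        raise ValueError(
            f"confidence_threshold must be in [0, 1], got {confidence_threshold}"
        )
    if "everything" not in backend.capabilities:
        raise ValueError(f"backend {backend.name!r} lacks 'everything' capability")
    proposals = backend.everything(image, confidence_threshold)
    return [m for m in proposals if m.score >= confidence_threshold]


def segment_boxes(
    backend: SegmenterBackend, image: np.ndarray, boxes: Sequence[BoxPrompt]
) -> List[SegmentMask]:
    """Box-prompted segmentation: one mask per box, order preserved."""
    if not boxes:
        raise ValueError("box list must be non-empty")
    if "boxes" not in backend.capabilities:
        raise ValueError(f"backend {backend.name!r} lacks 'boxes' capability")
    shape = image.shape[:2]
    for i, box in enumerate(boxes):
        if not box.intersects(shape):
            raise ValueError(f"box {i} ({box}) lies fully outside the image")
    masks = backend.from_boxes(image, list(boxes))
    if len(masks) != len(boxes):
        raise RuntimeError(
            f"backend {backend.name!r} returned {len(masks)} masks for "
            f"{len(boxes)} boxes"
        )
    return masks


def postprocess_masks(
    raw_masks: Sequence[SegmentMask],
    image_shape: Tuple[int, int],
    mode: SegmentationMode,
    threshold_used: float = 0.0,
) -> MaskSet:
    """Rank masks by area (largest first) and assign 1-based ids.

    Area ties keep the original proposal order.  An empty input yields a
    valid empty MaskSet.
    """
    for m in raw_masks:
        if m.raster.shape != tuple(image_shape):
            raise ValueError("all masks must share image_shape")
    order = sorted(range(len(raw_masks)), key=lambda i: (-raw_masks[i].area_px, i))
    ranked = [
        SegmentMask(mask_id=pos, raster=raw_masks[i].raster, score=raw_masks[i].score)
        for pos, i in enumerate(order, start=1)
    ]
    return MaskSet(
        masks=ranked,
        mode=SegmentationMode(mode),
        image_shape=tuple(image_shape),
        threshold_used=threshold_used,
    )


class ReferenceSegmenter:
    """Deterministic color-clustering segmenter.

    Everything-mode: k-means on RGB pixel values (seeded, capped
    iterations, ties to the lowest cluster index), then 8-connected
    components per color class; components of at least ``min_area_px``
    pixels become masks with score 1.0.  The color class holding the
    majority of border pixels is treated as background and proposes no
    masks.

    Boxes-mode: within each box, the largest connected component of
    non-background color.

    A pure function of (image, parameters, seed).
    """

    def __init__(self, k_colors: int = 4, min_area_px: int = 64, seed: int = 0):
        if k_colors < 2:
            raise ValueError("k_colors must be >= 2")
        self.k_colors = int(k_colors)
        self.min_area_px = int(min_area_px)
        self.seed = int(seed)
        self.name = "reference"
        self.capabilities = frozenset({"everything", "boxes"})

    # -- internals ---------------------------------------------------------

    def _color_classes(self, image: np.ndarray) -> Tuple[np.ndarray, int]:
        """Per-pixel cluster label map and the background label."""
        h, w = image.shape[:2]
        if h < 2 or w < 2:
            raise ValueError(f"image too small to segment: {h}x{w}")
        pixels = np.asarray(image, dtype=float).reshape(-1, 3)
        # cluster the distinct colors, then map labels back: exact for the
        # flat-color imagery this backend targets and much faster than
        # clustering every pixel
        uniq, inverse = np.unique(pixels, axis=0, return_inverse=True)
        k = min(self.k_colors, uniq.shape[0])
        if k < 2:
            labels = np.zeros(h * w, dtype=int)
        else:
            km = KMeans(
                n_clusters=k,
                n_init=1,
                max_iter=100,
                random_state=self.seed,
            ).fit(uniq)
            # re-index clusters by center order so labeling is stable in
            # the seed for well-separated colors
            center_order = np.lexsort(km.cluster_centers_.T[::-1])
            relabel = np.empty(k, dtype=int)
            relabel[center_order] = np.arange(k)
            labels = relabel[km.labels_][inverse]
        label_map = labels.reshape(h, w)
        border = np.concatenate(
            [label_map[0, :], label_map[-1, :], label_map[:, 0], label_map[:, -1]]
        )
        background = int(np.bincount(border).argmax())
        return label_map, background

    # -- backend contract --------------------------------------------------

    def everything(self, image: np.ndarray, threshold: float) -> List[SegmentMask]:
        label_map, background = self._color_classes(image)
        masks: List[SegmentMask] = []
        for cls in range(label_map.max() + 1):
            if cls == background:
                continue
            comp, n_comp = ndimage.label(label_map == cls, structure=_STRUCT8)
            for c in range(1, n_comp + 1):
                raster = comp == c
                if int(raster.sum()) >= self.min_area_px:
                    masks.append(SegmentMask(mask_id=0, raster=raster, score=1.0))
        return masks

    def from_boxes(
        self, image: np.ndarray, boxes: Sequence[BoxPrompt]
    ) -> List[SegmentMask]:
        label_map, background = self._color_classes(image)
        shape = image.shape[:2]
        out: List[SegmentMask] = []
        for i, box in enumerate(boxes):
            x0, y0, x1, y1 = box.clip(shape)
            window = np.zeros(shape, dtype=bool)
            window[y0:y1, x0:x1] = True
            fg = (label_map != background) & window
            if not fg.any():
                # uniform/background-only box: the whole box is the object
                out.append(SegmentMask(mask_id=0, raster=window, score=1.0))
                continue
            comp, n_comp = ndimage.label(fg, structure=_STRUCT8)
            sizes = ndimage.sum_labels(fg, comp, index=np.arange(1, n_comp + 1))
            best = int(np.argmax(sizes)) + 1
            out.append(SegmentMask(mask_id=0, raster=comp == best, score=1.0))
        return out


# Backend registry ----------------------------------------------------------

_REGISTRY: Dict[str, Callable[..., SegmenterBackend]] = {}


def register_backend(name: str, factory: Callable[..., SegmenterBackend]) -> None:
    _REGISTRY[name] = factory


def get_backend(name: str, **kwargs) -> SegmenterBackend:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown backend {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
    return factory(**kwargs)


register_backend("reference", ReferenceSegmenter)
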