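"""The egg-quantification pipeline: tile, detect, stitch, merge, filter, count.

An input leaf image is cropped to a multiple of the tile size, cut into padded
tiles, and a pluggable detector backend is run on every tile.  Per-tile boxes
are translated back to original-image coordinates and passed through three
post-processing stages, in this order:

1. *merge* — boxes with pairwise IoU above a threshold (default 0.5) are
   fused into their coordinate-wise envelope, so the same egg seen in two
   overlapping padded tiles is counted once;
2. *size filter* — boxes with either side below 20 px (trichome fragments,
   leaf spots) or above 90 px (nymphs, smears) are discarded;
3. *confidence threshold* — boxes below the detector-confidence cutoff
   (default 0.6) are discarded.

The number of surviving boxes is the egg count.  The trained-model seat is the
`DetectorBackend` protocol; `ReferenceBlobDetector` is a deterministic
classical backend sufficient for synthetic scenes, and `NullBackend` detects
nothing (useful for plumbing tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .geometry import (
    Box,
    CropPlan,
    ImageDims,
    TileSpec,
    extract_tile,
    pairwise_iou,
    plan_crop,
    plan_tiles,
    to_global,
)

__all__ = [
    "PipelineConfig",
    "DetectorBackend",
    "NullBackend",
    "ReferenceBlobDetector",
    "EggCountResult",
    "merge_detections",
    "filter_size",
    "filter_confidence",
    "quantify_image",
]

_ELLIPSE_FILL = math.pi / 4.0  # area of an ellipse / area of its bounding box


@dataclass(frozen=True)
class PipelineConfig:
    """Tiling and post-processing parameters with their standard defaults."""

    core_size_px: int = 1400
    padding_px: int = 100
    merge_iou_threshold: float = 0.5
    min_side_px: float = 20.0
    max_side_px: float = 90.0
    confidence_threshold: float = 0.6
    edge_policy: str = "reflect"

    def __post_init__(self) -> None:
        if not (0 < self.merge_iou_threshold <= 1):
            raise ValueError("merge_iou_threshold must be in (0, 1]")
        if not (0 <= self.confidence_threshold <= 1):
            raise ValueError("confidence_threshold must be in [0, 1]")
        if not (0 <= self.min_side_px < self.max_side_px):
            raise ValueError("need 0 <= min_side_px < max_side_px")
        if self.core_size_px < 1 or self.padding_px < 0:
            raise ValueError("invalid tile geometry")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@runtime_checkable
class DetectorBackend(Protocol):
    """Contract for a per-tile detector.

    ``detect`` receives one padded RGB tile (uint8, HxWx3) and returns boxes
    in tile-local pixel coordinates with confidences in [0, 1].  Any internal
    resizing is the backend's private concern.  A wrapper around a trained
    model (e.g. a YOLO-family network) plugs in here: run the model on the
    tile, convert its outputs to `Box` objects, and return them.
    """

    name: str

    def detect(self, tile: np.ndarray) -> list[Box]: ...


class NullBackend:
    """Detects nothing; the pipeline's identity element."""

    name = "null"

    def detect(self, tile: np.ndarray) -> list[Box]:
        return []


class ReferenceBlobDetector:
    """Classical egg detector for synthetic scenes.

    Eggs are the only scene objects whose red channel exceeds the green one,
    so thresholding R - G and taking connected components isolates candidate
    blobs.  Each component's confidence is a score in [0, 1] combining the
    fill ratio (component area over bounding-box area; an ellipse fills pi/4
    of its box), a gate on the box axis ratio (genuine eggs have an axis
    ratio near 0.4 and never drop much below ~0.25 even when rotated,
    whereas thin strands have extreme ratios and sparse fill and score
    < 0.5), and the mean R - G contrast of the component, which penalizes
    out-of-focus blobs.  Deterministic; operates at native tile resolution.
    """

    name = "reference"

    def __init__(
        self,
        channel_diff_threshold: int = 10,
        min_area_px: int = 60,
        full_contrast: float = 25.0,
    ):
        self.channel_diff_threshold = channel_diff_threshold
        self.min_area_px = min_area_px
        self.full_contrast = full_contrast

    def detect(self, tile: np.ndarray) -> list[Box]:
        if tile.ndim != 3 or tile.shape[-1] != 3:
            raise ValueError(f"expected an RGB tile, got shape {tile.shape}")
        diff = tile[..., 0].astype(np.int16) - tile[..., 1].astype(np.int16)
        mask = diff >= self.channel_diff_threshold
        out: list[Box] = []
        if not mask.any():
            return out
        for region in regionprops(cc_label(mask, connectivity=2), intensity_image=diff):
            if region.area < self.min_area_px:
                continue
            r0, c0, r1, c1 = region.bbox  # half-open
            w, h = c1 - c0, r1 - r0
            fill = region.area / (w * h)
            fill_score = min(fill / _ELLIPSE_FILL, 1.0)
            ratio = min(w, h) / max(w, h)
            gate = min(max((ratio - 0.08) / 0.17, 0.0), 1.0)
            contrast = min(float(region.intensity_mean) / self.full_contrast, 1.0)
            conf = min(max(gate * contrast * (0.38 + 0.60 * fill_score), 0.0), 1.0)
            out.append(Box(float(c0), float(r0), float(c1), float(r1), confidence=conf))
        return out


@dataclass(frozen=True)
class EggCountResult:
    """Final count for one image plus each post-processing stage's boxes."""

    image_id: str
    raw_boxes: tuple[Box, ...]  # post-stitch, pre-merge
    merged_boxes: tuple[Box, ...]
    size_filtered_boxes: tuple[Box, ...]
    final_boxes: tuple[Box, ...]
    config: PipelineConfig
    size_rejections: tuple[tuple[Box, str], ...] = ()

    def __post_init__(self) -> None:
        n = (len(self.raw_boxes), len(self.merged_boxes),
             len(self.size_filtered_boxes), len(self.final_boxes))
        if not (n[0] >= n[1] >= n[2] >= n[3]):
            raise ValueError(f"stage counts must be non-increasing, got {n}")

    @property
    def count(self) -> int:
        return len(self.final_boxes)


def _size_reason(b: Box, min_side: float, max_side: float) -> str | None:
    if min(b.width, b.height) < min_side:
        return "too_small"
    if max(b.width, b.height) > max_side:
        return "too_large"
    return None


def merge_detections(boxes: Sequence[Box], iou_threshold: float = 0.5) -> list[Box]:
    """Fuse overlapping duplicate detections into envelope boxes.

    All pairs with IoU strictly greater than ``iou_threshold`` are linked;
    every connected group is replaced by its coordinate-wise envelope (lowest
    x1/y1, highest x2/y2) with the maximum constituent confidence, and the
    procedure repeats on the new boxes until no pair exceeds the threshold.
    Merging whole connected groups at once makes the fixed point independent
    of input order; the result is sorted by (y1, x1) and the operation is
    idempotent.
    """
    current = list(boxes)
    while len(current) > 1:
        m = pairwise_iou(current, current)
        np.fill_diagonal(m, 0.0)
        if not (m > iou_threshold).any():
            break
        # union-find over the IoU graph
        parent = list(range(len(current)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        rows, cols = np.nonzero(m > iou_threshold)
        for i, j in zip(rows.tolist(), cols.tolist()):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
        groups: dict[int, list[Box]] = {}
        for i, b in enumerate(current):
            groups.setdefault(find(i), []).append(b)
        current = [
            Box(
                x1=min(b.x1 for b in grp),
                y1=min(b.y1 for b in grp),
                x2=max(b.x2 for b in grp),
                y2=max(b.y2 for b in grp),
                confidence=max(b.confidence for b in grp),
                label=grp[0].label,
            )
            for grp in groups.values()
        ]
    return sorted(current, key=lambda b: (b.y1, b.x1, b.y2, b.x2))


def filter_size(
    boxes: Sequence[Box], min_side_px: float = 20.0, max_side_px: float = 90.0
) -> list[Box]:
    """Keep boxes whose sides all lie within [min_side_px, max_side_px]."""
    return [b for b in boxes if _size_reason(b, min_side_px, max_side_px) is None]


def filter_confidence(boxes: Sequence[Box], tau: float) -> list[Box]:
    """Keep boxes with confidence >= tau (the boundary is kept)."""
    if not (0 <= tau <= 1):
        raise ValueError("tau must be in [0, 1]")
    return [b for b in boxes if b.confidence >= tau]


def _collect_raw_boxes(
    image: np.ndarray,
    backend: DetectorBackend,
    crop: CropPlan,
    tiles: Sequence[TileSpec],
    config: PipelineConfig,
) -> list[Box]:
    h, w = crop.original_dims.length_px, crop.original_dims.width_px
    raw: list[Box] = []
    for tile in tiles:
        block = extract_tile(image, tile, crop, edge_policy=config.edge_policy)
        try:
            dets = backend.detect(block)
        except Exception as exc:  # noqa: BLE001 - annotate with tile position
            raise RuntimeError(
                f"backend '{backend.name}' failed on tile "
                f"({tile.row_index}, {tile.col_index}): {exc}"
            ) from exc
        size = tile.padded_size_px
        for b in dets:
            # With padding, a box touching the padded frame is a partial view
            # of an object that some neighbouring tile sees in full (the
            # padding exceeds the egg size); keep only complete views so that
            # merge sees near-identical duplicates rather than slivers.
            if config.padding_px > 0 and (
                b.x1 <= 0.5 or b.y1 <= 0.5 or b.x2 >= size - 0.5 or b.y2 >= size - 0.5
            ):
                continue
            g = to_global(b, tile, crop)
            # clip to the original image; drop boxes entirely outside it
            # (reflection phantoms from edge tiles)
            x1, y1 = max(g.x1, 0.0), max(g.y1, 0.0)
            x2, y2 = min(g.x2, float(w)), min(g.y2, float(h))
            if x2 <= x1 or y2 <= y1:
                continue
            raw.append(replace(g, x1=x1, y1=y1, x2=x2, y2=y2))
    return raw


def quantify_image(
    image: np.ndarray,
    backend: DetectorBackend,
    config: PipelineConfig | None = None,
    image_id: str = "image",
) -> EggCountResult:
    """Run the full quantification pipeline on one RGB image.

    Stages run in fixed order: crop plan, tile plan, per-tile detection,
    translation to global coordinates (clipped to the image), duplicate
    merging, size filtering, confidence thresholding.  Deterministic given a
    deterministic backend.  Raises a geometry error for images smaller than
    one tile and a ``RuntimeError`` naming the tile if the backend fails.
    """
    config = config or PipelineConfig()
    dims = ImageDims(int(image.shape[0]), int(image.shape[1]))
    crop = plan_crop(dims, config.core_size_px)
    tiles = plan_tiles(crop, config.core_size_px, config.padding_px)
    raw = _collect_raw_boxes(image, backend, crop, tiles, config)
    merged = merge_detections(raw, config.merge_iou_threshold)
    rejections = tuple(
        (b, reason)
        for b in merged
        if (reason := _size_reason(b, config.min_side_px, config.max_side_px))
    )
    sized = filter_size(merged, config.min_side_px, config.max_side_px)
    final = filter_confidence(sized, config.confidence_threshold)
    return EggCountResult(
        image_id=image_id,
        raw_boxes=tuple(raw),
        merged_boxes=tuple(merged),
        size_filtered_boxes=tuple(sized),
        final_boxes=tuple(final),
        config=config,
        size_rejections=rejections,
    )
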