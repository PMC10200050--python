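"""Image-plane arithmetic for tiled detection.

Large leaf scans are cut into fixed-size square tiles so that sub-millimetre
eggs stay resolvable to a detector.  The image is first cropped to an exact
multiple of the tile size (the surplus is removed evenly from opposite sides),
each tile is then extracted with a symmetric pixel padding so that objects
sitting on a tile boundary are fully visible in at least one padded tile, and
per-tile detections are finally translated back into original-image
coordinates.

Coordinate conventions: 0-based, half-open intervals ``[x1, x2) x [y1, y2)``
with ``x`` = column and ``y`` = row.  Areas are therefore plain products of
side lengths with no ``+1`` corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from shapely import box as _shapely_box
from shapely.ops import unary_union

__all__ = [
    "ImageDims",
    "CropPlan",
    "TileSpec",
    "Box",
    "plan_crop",
    "plan_tiles",
    "extract_tile",
    "to_global",
    "iou",
    "pairwise_iou",
]


@dataclass(frozen=True)
class ImageDims:
    """Height (``length_px``) and width of an image, in pixels."""

    length_px: int
    width_px: int

    def __post_init__(self) -> None:
        if self.length_px < 1 or self.width_px < 1:
            raise ValueError(f"image dims must be >= 1, got {self}")


@dataclass(frozen=True)
class CropPlan:
    """How an image is trimmed to an exact multiple of the tile size.

    ``surplus_length_px``/``surplus_width_px`` pixels are removed per axis,
    split as evenly as possible between the two opposite sides (an odd surplus
    puts the extra pixel on the bottom/right).  ``offset_top``/``offset_left``
    give the origin of the cropped image inside the original one.
    """

    surplus_length_px: int
    surplus_width_px: int
    offset_top: int
    offset_left: int
    cropped_dims: ImageDims
    original_dims: ImageDims

    def __post_init__(self) -> None:
        if min(self.surplus_length_px, self.surplus_width_px) < 0:
            raise ValueError("surplus must be non-negative")
        if (
            self.cropped_dims.length_px + self.surplus_length_px
            != self.original_dims.length_px
            or self.cropped_dims.width_px + self.surplus_width_px
            != self.original_dims.width_px
        ):
            raise ValueError("cropped dims + surplus must equal original dims")


@dataclass(frozen=True)
class TileSpec:
    """One tile: its core region in cropped-image pixels plus padding.

    The core regions of all tiles partition the cropped image exactly; the
    padded window extends ``padding_px`` beyond the core on every side (and may
    extend beyond the cropped image itself — `extract_tile` decides how those
    pixels are filled).
    """

    row_index: int
    col_index: int
    core_origin: tuple[int, int]  # (row, col) in cropped-image pixels
    core_size_px: int = 1400
    padding_px: int = 100

    def __post_init__(self) -> None:
        if self.core_size_px < 1 or self.padding_px < 0:
            raise ValueError("invalid tile geometry")
        r, c = self.core_origin
        if r % self.core_size_px or c % self.core_size_px:
            raise ValueError("core_origin must be a multiple of core_size_px")

    @property
    def padded_origin(self) -> tuple[int, int]:
        r, c = self.core_origin
        return (r - self.padding_px, c - self.padding_px)

    @property
    def padded_size_px(self) -> int:
        return self.core_size_px + 2 * self.padding_px


@dataclass(frozen=True)
class Box:
    """Axis-aligned box ``[x1, x2) x [y1, y2)`` with a detection confidence.

    Coordinates are pixel positions in whatever frame the box lives in
    (tile-local or global); they may be fractional.  Boxes emitted by the
    quantification pipeline are clipped to the image, so their coordinates are
    additionally non-negative.
    """

    x1: float
    y1: float
    x2: float
    y2: float
    confidence: float = 1.0
    label: str = "egg"

    def __post_init__(self) -> None:
        coords = (self.x1, self.y1, self.x2, self.y2)
        if not all(math.isfinite(v) for v in coords):
            raise ValueError(f"non-finite box coordinates {coords}")
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"degenerate box {coords}")
        if not math.isfinite(self.confidence):
            raise ValueError("non-finite confidence")

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    def translate(self, dx: float, dy: float) -> "Box":
        return replace(
            self, x1=self.x1 + dx, y1=self.y1 + dy, x2=self.x2 + dx, y2=self.y2 + dy
        )

    def intersection_area(self, other: "Box") -> float:
        w = min(self.x2, other.x2) - max(self.x1, other.x1)
        h = min(self.y2, other.y2) - max(self.y1, other.y1)
        return w * h if (w > 0 and h > 0) else 0.0


def plan_crop(dims: ImageDims, core_size_px: int = 1400) -> CropPlan:
    """Plan the surplus-removing crop that makes ``dims`` tile exactly.

    The surplus per axis is ``dims mod core_size_px``, removed evenly from the
    two opposite sides; an odd surplus leaves the extra pixel to remove on the
    bottom (length axis) / right (width axis).

    Raises ``ValueError`` if the image is smaller than one tile.
    """
    if core_size_px < 1:
        raise ValueError("core_size_px must be >= 1")
    if dims.length_px < core_size_px or dims.width_px < core_size_px:
        raise ValueError(
            f"image too small: {dims.length_px}x{dims.width_px} px cannot hold "
            f"one {core_size_px}x{core_size_px} tile"
        )
    s_l = dims.length_px % core_size_px
    s_w = dims.width_px % core_size_px
    return CropPlan(
        surplus_length_px=s_l,
        surplus_width_px=s_w,
        offset_top=s_l // 2,
        offset_left=s_w // 2,
        cropped_dims=ImageDims(dims.length_px - s_l, dims.width_px - s_w),
        original_dims=dims,
    )


def plan_tiles(
    crop: CropPlan, core_size_px: int = 1400, padding_px: int = 100
) -> list[TileSpec]:
    """Row-major list of tiles whose cores partition the cropped image."""
    if crop.cropped_dims.length_px % core_size_px or crop.cropped_dims.width_px % core_size_px:
        raise ValueError("cropped dims must be exact multiples of core_size_px")
    n_rows = crop.cropped_dims.length_px // core_size_px
    n_cols = crop.cropped_dims.width_px // core_size_px
    return [
        TileSpec(
            row_index=i,
            col_index=j,
            core_origin=(i * core_size_px, j * core_size_px),
            core_size_px=core_size_px,
            padding_px=padding_px,
        )
        for i in range(n_rows)
        for j in range(n_cols)
    ]


def extract_tile(
    image: np.ndarray,
    tile: TileSpec,
    crop: CropPlan,
    edge_policy: str = "reflect",
) -> np.ndarray:
    """Cut one padded tile out of the *original* image.

    The padded window is positioned in original-image coordinates, so padding
    that reaches beyond the cropped region is filled with real surplus pixels
    whenever they exist; only where the window leaves the original image is it
    filled synthetically per ``edge_policy`` (any ``numpy.pad`` mode; default
    ``"reflect"``, which avoids fabricated dark borders).
    """
    if image.shape[0] != crop.original_dims.length_px or image.shape[1] != crop.original_dims.width_px:
        raise ValueError(
            f"image shape {image.shape[:2]} does not match crop plan dims "
            f"({crop.original_dims.length_px}, {crop.original_dims.width_px})"
        )
    size = tile.padded_size_px
    r0 = tile.padded_origin[0] + crop.offset_top
    c0 = tile.padded_origin[1] + crop.offset_left
    r1, c1 = r0 + size, c0 + size
    h, w = image.shape[:2]
    # real-pixel part of the window
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, h), min(c1, w)
    block = image[rr0:rr1, cc0:cc1]
    pad = (
        (rr0 - r0, r1 - rr1),
        (cc0 - c0, c1 - cc1),
    ) + ((0, 0),) * (image.ndim - 2)
    if any(p for pair in pad for p in pair):
        block = np.pad(block, pad, mode=edge_policy)
    return block


def to_global(box: Box, tile: TileSpec, crop: CropPlan) -> Box:
    """Translate a tile-local box into original-image coordinates.

    Pure translation by the tile's padded origin plus the crop offsets, so
    ``to_global`` followed by the inverse shift is the identity; confidence and
    label are untouched.  The box must lie within the tile's padded extent.
    """
    size = tile.padded_size_px
    if not (0 <= box.x1 and box.x2 <= size and 0 <= box.y1 and box.y2 <= size):
        raise ValueError(
            f"box ({box.x1}, {box.y1}, {box.x2}, {box.y2}) outside the "
            f"{size}x{size} padded tile extent"
        )
    dy = tile.padded_origin[0] + crop.offset_top
    dx = tile.padded_origin[1] + crop.offset_left
    return box.translate(dx, dy)


def _pair_iou(a: Box, b: Box) -> float:
    inter = a.intersection_area(b)
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


def iou(boxes: Box | Sequence[Box]) -> float:
    """Intersection-over-union of one or more boxes.

    ``area(B1 ∩ ... ∩ Bk) / area(B1 ∪ ... ∪ Bk)``.  A single box gives 1.0.
    The two-box case is closed-form inclusion–exclusion; for k > 2 the union
    area is computed exactly via shapely's polygon union.
    """
    if isinstance(boxes, Box):
        boxes = [boxes]
    boxes = list(boxes)
    if not boxes:
        raise ValueError("iou requires at least one box")
    if len(boxes) == 1:
        return 1.0
    if len(boxes) == 2:
        return _pair_iou(boxes[0], boxes[1])
    ix1 = max(b.x1 for b in boxes)
    iy1 = max(b.y1 for b in boxes)
    ix2 = min(b.x2 for b in boxes)
    iy2 = min(b.y2 for b in boxes)
    inter = max(0.0, ix2 - ix1) * max(0.0, iy2 - iy1)
    if inter == 0.0:
        return 0.0
    union = unary_union([_shapely_box(b.x1, b.y1, b.x2, b.y2) for b in boxes]).area
    return inter / union


def pairwise_iou(a: Iterable[Box], b: Iterable[Box]) -> np.ndarray:
    """Matrix of pairwise IoU values, shape ``(len(a), len(b))``."""
    aa = np.array([(x.x1, x.y1, x.x2, x.y2) for x in a], dtype=float).reshape(-1, 4)
    bb = np.array([(x.x1, x.y1, x.x2, x.y2) for x in b], dtype=float).reshape(-1, 4)
    if aa.size == 0 or bb.size == 0:
        return np.zeros((aa.shape[0], bb.shape[0]))
    iw = np.minimum(aa[:, None, 2], bb[None, :, 2]) - np.maximum(aa[:, None, 0], bb[None, :, 0])
    ih = np.minimum(aa[:, None, 3], bb[None, :, 3]) - np.maximum(aa[:, None, 1], bb[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    area_a = (aa[:, 2] - aa[:, 0]) * (aa[:, 3] - aa[:, 1])
    area_b = (bb[:, 2] - bb[:, 0]) * (bb[:, 3] - bb[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(inter > 0, inter / union, 0.0)
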