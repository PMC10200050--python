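"""Seeded generator of microscope-like leaf scenes with exact ground truth.

Whitefly eggs on the abaxial leaf surface appear under ~30x magnification as
small high-contrast ellipses (bounding boxes roughly 22-88 px across, axis
ratio near 0.4 — the egg is ~0.2 mm long and ~0.08 mm wide) on a textured
green background, surrounded by confounders: thin pale trichome strands,
translucent honeydew deposits, dark leaf spots, and locally blurred regions
where the leaf curls out of focus.  This module renders such scenes from a
seeded random stream together with the exact axis-aligned bounds of every
rendered egg, so the detection pipeline and its evaluation can be exercised
end-to-end without any real imagery.

Ground-truth boxes are the exact analytic bounds of each ellipse (not
dilated); detectors must cope with anti-aliased edges on their own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter

from .geometry import Box

__all__ = [
    "SceneConfig",
    "EggTruth",
    "Distractor",
    "SceneTruth",
    "generate_scene",
    "render_scene",
    "simulate_detections",
]

# Rendering palette (8-bit RGB). Eggs are the only objects whose red channel
# exceeds the green one, which is what the reference detector keys on.
BACKGROUND_RGB = (58.0, 105.0, 48.0)
EGG_FRESH_RGB = (162.0, 128.0, 74.0)  # translucent green-olive, freshly laid
EGG_MATURE_RGB = (120.0, 72.0, 45.0)  # brown, close to hatching
TRICHOME_RGB = (215.0, 220.0, 205.0)
SPOT_RGB = (115.0, 75.0, 48.0)
HONEYDEW_BRIGHTEN = 28.0


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic leaf scene.

    Egg geometry defaults follow the observed bounding-box statistics of real
    eggs (shortest side 22 px, longest 88 px, axis ratio near 0.4).  A fixed
    ``seed`` makes the scene bit-identical across runs.
    """

    height_px: int = 2800
    width_px: int = 2800
    n_eggs: int = 60
    egg_minor_px: tuple[float, float] = (22.0, 40.0)
    egg_max_side_px: float = 88.0
    egg_axis_ratio: tuple[float, float] = (0.40, 0.55)
    min_center_distance_px: float = 120.0
    n_trichomes: int = 0
    n_honeydew_blobs: int = 0
    n_specks: int = 0  # sub-20-px dark specks (size-filter bait)
    n_smears: int = 0  # >90-px elongated smears (size-filter bait)
    n_blur_patches: int = 0
    blur_sigma: float = 6.0
    edge_margin_px: float = 4.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1 or self.n_eggs < 0:
            raise ValueError("invalid scene dimensions or egg count")
        if self.egg_minor_px[0] <= 0 or self.egg_minor_px[0] > self.egg_minor_px[1]:
            raise ValueError("invalid egg minor-axis range")
        if not (0 < self.egg_axis_ratio[0] <= self.egg_axis_ratio[1] <= 1):
            raise ValueError("egg axis ratio must lie in (0, 1]")


@dataclass(frozen=True)
class EggTruth:
    """One rendered egg: ellipse parameters plus its exact bounding box."""

    center: tuple[float, float]  # (x, y)
    semi_major: float
    semi_minor: float
    angle_rad: float
    maturity: float  # 0 = translucent green, 1 = brown
    box: Box


@dataclass(frozen=True)
class Distractor:
    kind: str  # trichome | honeydew | speck | smear | blur
    params: dict


@dataclass(frozen=True)
class SceneTruth:
    config: SceneConfig
    eggs: tuple[EggTruth, ...]
    distractors: tuple[Distractor, ...] = ()

    @property
    def boxes(self) -> list[Box]:
        return [e.box for e in self.eggs]


def _ellipse_bbox_half_extents(a: float, b: float, angle: float) -> tuple[float, float]:
    """Half width/height of the tight axis-aligned bounds of a rotated ellipse."""
    c, s = math.cos(angle), math.sin(angle)
    hw = math.sqrt((a * c) ** 2 + (b * s) ** 2)
    hh = math.sqrt((a * s) ** 2 + (b * c) ** 2)
    return hw, hh


def _place(
    rng: np.random.Generator,
    placed: list[tuple[float, float, float]],
    radius: float,
    hw: float,
    hh: float,
    cfg: SceneConfig,
    min_dist: float,
    what: str,
    max_attempts: int = 4000,
) -> tuple[float, float]:
    """Rejection-sample a center keeping the object inside the image and away
    from previously placed objects; raises when the constraint is infeasible."""
    m = cfg.edge_margin_px
    lo_x, hi_x = m + hw, cfg.width_px - m - hw
    lo_y, hi_y = m + hh, cfg.height_px - m - hh
    if lo_x >= hi_x or lo_y >= hi_y:
        raise ValueError(f"cannot place {what}: object larger than the usable canvas")
    for _ in range(max_attempts):
        cx = rng.uniform(lo_x, hi_x)
        cy = rng.uniform(lo_y, hi_y)
        ok = True
        for (px, py, pr) in placed:
            need = max(min_dist, radius + pr + 10.0)
            if (cx - px) ** 2 + (cy - py) ** 2 < need**2:
                ok = False
                break
        if ok:
            placed.append((cx, cy, radius))
            return cx, cy
    raise ValueError(
        f"cannot place {what}: minimum spacing {min_dist:.0f} px infeasible on a "
        f"{cfg.height_px}x{cfg.width_px} canvas after {max_attempts} attempts"
    )


def generate_scene(config: SceneConfig) -> SceneTruth:
    """Sample egg and distractor layouts; deterministic for a given seed."""
    rng = np.random.default_rng(config.seed)
    placed: list[tuple[float, float, float]] = []
    eggs: list[EggTruth] = []
    for _ in range(config.n_eggs):
        minor = rng.uniform(*config.egg_minor_px)
        ratio = rng.uniform(*config.egg_axis_ratio)
        major = min(minor / ratio, config.egg_max_side_px)
        a, b = major / 2.0, minor / 2.0
        angle = rng.uniform(0.0, math.pi)
        hw, hh = _ellipse_bbox_half_extents(a, b, angle)
        cx, cy = _place(
            rng, placed, a, hw, hh, config, config.min_center_distance_px, "egg"
        )
        eggs.append(
            EggTruth(
                center=(cx, cy),
                semi_major=a,
                semi_minor=b,
                angle_rad=angle,
                maturity=float(rng.uniform(0.0, 1.0)),
                box=Box(cx - hw, cy - hh, cx + hw, cy + hh),
            )
        )

    distractors: list[Distractor] = []
    for _ in range(config.n_smears):
        major = rng.uniform(110.0, 150.0)
        minor = rng.uniform(26.0, 38.0)
        angle = math.radians(rng.uniform(-15.0, 15.0))
        hw, hh = _ellipse_bbox_half_extents(major / 2, minor / 2, angle)
        cx, cy = _place(rng, placed, major / 2, hw, hh, config, 0.0, "smear")
        distractors.append(
            Distractor(
                "smear",
                {"center": (cx, cy), "semi_major": major / 2, "semi_minor": minor / 2,
                 "angle_rad": angle},
            )
        )
    for _ in range(config.n_specks):
        d = rng.uniform(6.0, 12.0)
        cx, cy = _place(rng, placed, d / 2, d / 2, d / 2, config, 0.0, "speck")
        distractors.append(Distractor("speck", {"center": (cx, cy), "radius": d / 2}))
    for _ in range(config.n_honeydew_blobs):
        r = rng.uniform(18.0, 55.0)
        cx = rng.uniform(r, config.width_px - r)
        cy = rng.uniform(r, config.height_px - r)
        distractors.append(Distractor("honeydew", {"center": (cx, cy), "radius": r}))
    for _ in range(config.n_trichomes):
        # random-walk polyline: start, heading, ~fixed-length jittered steps
        x = rng.uniform(0, config.width_px)
        y = rng.uniform(0, config.height_px)
        heading = rng.uniform(0, 2 * math.pi)
        pts = [(x, y)]
        for _ in range(rng.integers(40, 90)):
            heading += rng.normal(0.0, 0.25)
            x = min(max(x + 4.0 * math.cos(heading), 0), config.width_px - 1)
            y = min(max(y + 4.0 * math.sin(heading), 0), config.height_px - 1)
            pts.append((x, y))
        distractors.append(Distractor("trichome", {"points": pts}))
    for _ in range(config.n_blur_patches):
        r = rng.uniform(80.0, 160.0)
        cx = rng.uniform(0, config.width_px)
        cy = rng.uniform(0, config.height_px)
        distractors.append(
            Distractor("blur", {"center": (cx, cy), "radius": r, "sigma": config.blur_sigma})
        )
    return SceneTruth(config=config, eggs=tuple(eggs), distractors=tuple(distractors))


def _paint_ellipse(
    img: np.ndarray,
    center: tuple[float, float],
    a: float,
    b: float,
    angle: float,
    color: Sequence[float],
) -> None:
    """Alpha-composite an anti-aliased rotated ellipse onto ``img`` in place."""
    h, w = img.shape[:2]
    cx, cy = center
    hw, hh = _ellipse_bbox_half_extents(a, b, angle)
    x0, x1 = max(int(cx - hw) - 2, 0), min(int(cx + hw) + 3, w)
    y0, y1 = max(int(cy - hh) - 2, 0), min(int(cy + hh) + 3, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs + 0.5 - cx
    dy = ys + 0.5 - cy
    c, s = math.cos(angle), math.sin(angle)
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    q = u * u + v * v
    # ~1 px anti-aliasing band around q = 1
    alpha = np.clip(0.5 + (1.0 - q) * min(a, b) / 2.0, 0.0, 1.0)
    patch = img[y0:y1, x0:x1]
    patch += alpha[..., None] * (np.asarray(color, dtype=np.float32) - patch)


def _paint_disc_brighten(
    img: np.ndarray, center: tuple[float, float], radius: float, amount: float
) -> None:
    """Brighten a soft-edged disc equally in all channels (honeydew sheen)."""
    h, w = img.shape[:2]
    cx, cy = center
    x0, x1 = max(int(cx - radius) - 2, 0), min(int(cx + radius) + 3, w)
    y0, y1 = max(int(cy - radius) - 2, 0), min(int(cy + radius) + 3, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((xs + 0.5 - cx) ** 2 + (ys + 0.5 - cy) ** 2)
    alpha = np.clip(radius - d + 0.5, 0.0, 1.0) * np.clip(1.0 - d / (radius + 1e-9), 0.2, 1.0)
    img[y0:y1, x0:x1] += (amount * alpha)[..., None]


def _draw_polyline_mask(shape: tuple[int, int], points: Sequence[tuple[float, float]]) -> np.ndarray:
    from skimage.draw import line

    mask = np.zeros(shape, dtype=bool)
    for (xa, ya), (xb, yb) in zip(points[:-1], points[1:]):
        rr, cc = line(int(ya), int(xa), int(yb), int(xb))
        mask[rr, cc] = True
    return mask


def render_scene(truth: SceneTruth) -> np.ndarray:
    """Render a scene as an 8-bit RGB image; deterministic for the scene seed."""
    cfg = truth.config
    h, w = cfg.height_px, cfg.width_px
    rng = np.random.default_rng([cfg.seed, 0xC0FFEE % (2**31)])

    img = np.empty((h, w, 3), dtype=np.float32)
    img[:] = np.asarray(BACKGROUND_RGB, dtype=np.float32)
    # low-frequency leaf texture: equal-channel luminance undulation
    step = 16
    low = gaussian_filter(
        rng.standard_normal((h // step + 2, w // step + 2), dtype=np.float32), 3.0
    )
    tex = np.repeat(np.repeat(low, step, axis=0), step, axis=1)[:h, :w]
    tex *= 9.0
    img += tex[..., None]
    # per-pixel sensor noise
    noise = rng.standard_normal(img.shape, dtype=np.float32)
    noise *= cfg.noise_sigma
    img += noise

    for d in truth.distractors:
        if d.kind == "honeydew":
            _paint_disc_brighten(img, d.params["center"], d.params["radius"], HONEYDEW_BRIGHTEN)

    for egg in truth.eggs:
        color = np.asarray(EGG_FRESH_RGB) + egg.maturity * (
            np.asarray(EGG_MATURE_RGB) - np.asarray(EGG_FRESH_RGB)
        )
        _paint_ellipse(
            img, egg.center, egg.semi_major, egg.semi_minor, egg.angle_rad, color
        )

    for d in truth.distractors:
        if d.kind == "speck":
            _paint_ellipse(img, d.params["center"], d.params["radius"], d.params["radius"], 0.0, SPOT_RGB)
        elif d.kind == "smear":
            _paint_ellipse(
                img, d.params["center"], d.params["semi_major"], d.params["semi_minor"],
                d.params["angle_rad"], SPOT_RGB,
            )

    trichome_pts = [d.params["points"] for d in truth.distractors if d.kind == "trichome"]
    if trichome_pts:
        mask = np.zeros((h, w), dtype=bool)
        for pts in trichome_pts:
            mask |= _draw_polyline_mask((h, w), pts)
        mask = binary_dilation(mask, iterations=1)  # ~3 px wide strands
        img[mask] += 0.85 * (np.asarray(TRICHOME_RGB, dtype=np.float32) - img[mask])

    for d in truth.distractors:
        if d.kind == "blur":
            cx, cy = d.params["center"]
            r, sigma = d.params["radius"], d.params["sigma"]
            x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, w)
            y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, h)
            if x0 >= x1 or y0 >= y1:
                continue
            sub = img[y0:y1, x0:x1]
            blurred = gaussian_filter(sub, sigma=(sigma, sigma, 0))
            ys, xs = np.mgrid[y0:y1, x0:x1]
            dist = np.sqrt((xs + 0.5 - cx) ** 2 + (ys + 0.5 - cy) ** 2)
            alpha = np.clip((r - dist) / 10.0, 0.0, 1.0)[..., None]
            img[y0:y1, x0:x1] = sub + alpha * (blurred - sub)

    np.clip(img, 0, 255, out=img)
    return img.astype(np.uint8)


def simulate_detections(
    truth: SceneTruth,
    jitter_sigma: float = 1.0,
    fn_rate: float = 0.0,
    fp_rate: float = 0.0,
    tp_confidence: tuple[float, float] = (0.65, 1.0),
    fp_confidence: tuple[float, float] = (0.30, 0.60),
    seed: int = 0,
) -> list[Box]:
    """Draw a noisy detection set straight from the ground truth.

    Truth boxes are corner-jittered (``jitter_sigma`` px), dropped i.i.d. with
    probability ``fn_rate``, and Poisson(``fp_rate`` x n_eggs) false positives
    of egg-like size are scattered over the image.  True and false boxes draw
    confidences from separate uniform ranges, so confidence-threshold sweeps
    have a controlled signal to find.  Useful for exercising evaluation code
    without rendering or running a detector.
    """
    if not (0 <= fn_rate <= 1 and fp_rate >= 0):
        raise ValueError("rates must satisfy 0 <= fn_rate <= 1 and fp_rate >= 0")
    rng = np.random.default_rng(seed)
    cfg = truth.config
    out: list[Box] = []
    for egg in truth.eggs:
        if rng.random() < fn_rate:
            continue
        b = egg.box
        j = rng.normal(0.0, jitter_sigma, size=4) if jitter_sigma > 0 else np.zeros(4)
        x1, y1, x2, y2 = b.x1 + j[0], b.y1 + j[1], b.x2 + j[2], b.y2 + j[3]
        if x2 <= x1 or y2 <= y1:
            continue
        conf = 1.0 if jitter_sigma == 0 and fn_rate == 0 and fp_rate == 0 else float(
            rng.uniform(*tp_confidence)
        )
        out.append(Box(x1, y1, x2, y2, confidence=conf))
    n_fp = int(rng.poisson(fp_rate * max(len(truth.eggs), 1)))
    for _ in range(n_fp):
        bw = rng.uniform(20.0, 90.0)
        bh = rng.uniform(20.0, 90.0)
        x1 = rng.uniform(0.0, max(cfg.width_px - bw, 1.0))
        y1 = rng.uniform(0.0, max(cfg.height_px - bh, 1.0))
        out.append(Box(x1, y1, x1 + bw, y1 + bh, confidence=float(rng.uniform(*fp_confidence))))
    return out
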