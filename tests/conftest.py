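"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ovicount.geometry import Box


def rasterized_iou(boxes: list[Box], canvas: int = 64) -> float:
    """Pixel-counting IoU oracle for integer-coordinate boxes on a canvas."""
    inter = np.ones((canvas, canvas), dtype=bool)
    union = np.zeros((canvas, canvas), dtype=bool)
    for b in boxes:
        m = np.zeros((canvas, canvas), dtype=bool)
        m[int(b.y1):int(b.y2), int(b.x1):int(b.x2)] = True
        inter &= m
        union |= m
    u = union.sum()
    return inter.sum() / u if u else 0.0


def random_int_box(rng: np.random.Generator, canvas: int = 64,
                   max_side: int = 40, confidence: float = 1.0) -> Box:
    w = int(rng.integers(1, max_side))
    h = int(rng.integers(1, max_side))
    x1 = int(rng.integers(0, canvas - w))
    y1 = int(rng.integers(0, canvas - h))
    return Box(x1, y1, x1 + w, y1 + h, confidence=confidence)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230520)
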