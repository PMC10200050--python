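"""Readers/writers for images, box annotations, and pipeline configs.

Two annotation dialects are supported and both are converted to 0-based
half-open pixel boxes on read:

* YOLO text: one line per box, ``class cx cy w h [confidence]``, all
  coordinates normalized to the image size.
* CSV: header ``image,x1,y1,x2,y2,confidence,label`` in pixel coordinates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .geometry import Box

BOX_CSV_COLUMNS = ["image", "x1", "y1", "x2", "y2", "confidence", "label"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF/JPEG), dropping any alpha channel."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return np.ascontiguousarray(arr)


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def read_yolo(
    path: str | Path,
    image_width: int,
    image_height: int,
    class_names: Sequence[str] = ("egg",),
) -> list[Box]:
    """Read YOLO-format normalized boxes into pixel half-open boxes."""
    boxes: list[Box] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) not in (5, 6):
            raise ValueError(f"{path}:{lineno}: expected 5 or 6 fields, got {len(parts)}")
        cls = int(parts[0])
        cx, cy, w, h = (float(v) for v in parts[1:5])
        conf = float(parts[5]) if len(parts) == 6 else 1.0
        boxes.append(
            Box(
                x1=(cx - w / 2) * image_width,
                y1=(cy - h / 2) * image_height,
                x2=(cx + w / 2) * image_width,
                y2=(cy + h / 2) * image_height,
                confidence=conf,
                label=class_names[cls],
            )
        )
    return boxes


def write_yolo(
    path: str | Path,
    boxes: Sequence[Box],
    image_width: int,
    image_height: int,
    class_names: Sequence[str] = ("egg",),
    write_confidence: bool = False,
) -> None:
    lines = []
    for b in boxes:
        cls = class_names.index(b.label)
        cx = (b.x1 + b.x2) / 2 / image_width
        cy = (b.y1 + b.y2) / 2 / image_height
        w = b.width / image_width
        h = b.height / image_height
        rec = f"{cls} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
        if write_confidence:
            rec += f" {b.confidence:.4f}"
        lines.append(rec)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_boxes_csv(path: str | Path) -> dict[str, list[Box]]:
    """Read the CSV dialect; returns a mapping image id -> boxes."""
    df = pd.read_csv(path)
    missing = set(BOX_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[Box]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.image), []).append(
            Box(
                x1=float(row.x1),
                y1=float(row.y1),
                x2=float(row.x2),
                y2=float(row.y2),
                confidence=float(row.confidence),
                label=str(row.label),
            )
        )
    return out


def write_boxes_csv(path: str | Path, boxes_by_image: Mapping[str, Sequence[Box]]) -> None:
    records = [
        (image, b.x1, b.y1, b.x2, b.y2, b.confidence, b.label)
        for image, boxes in boxes_by_image.items()
        for b in boxes
    ]
    pd.DataFrame(records, columns=BOX_CSV_COLUMNS).to_csv(path, index=False)


def load_config_file(path: str | Path) -> dict:
    """Load a flat key/value pipeline-config file (YAML syntax)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config file must be a flat mapping")
    return data
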