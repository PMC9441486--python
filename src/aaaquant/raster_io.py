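"""Reading and writing slide rasters and indexed annotation maps.

Slides are 24-bit RGB PNG/TIFF; annotations are palette-indexed PNG
where the pixel value is the class index and the palette carries the
display colors (zone1 blue, zone2 green, thrombus red, background
purple, ignore gray).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .classes import CLASS_ORDER, PALETTE


def save_rgb(path: str | Path, image: np.ndarray) -> None:
    """Write an RGB raster (uint8 or float in [0, 255]) as 24-bit PNG/TIFF."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.round(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


def load_rgb(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def save_indexed(path: str | Path, labels: np.ndarray,
                 class_order: tuple[str, ...] = CLASS_ORDER) -> None:
    """Write an integer label raster as a palette-indexed PNG."""
    labels = np.asarray(labels)
    if labels.max(initial=0) >= len(class_order):
        raise ValueError("label value outside class order")
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    palette = []
    for name in class_order:
        palette.extend(PALETTE.get(name, (0, 0, 0)))
    img.putpalette(palette)
    img.save(path)


def load_indexed(path: str | Path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "P":
        raise ValueError(f"{path} is not a palette-indexed image")
    return np.asarray(img, dtype=np.uint8)
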