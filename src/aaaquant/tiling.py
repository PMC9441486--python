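"""Mosaic tiling of whole slides and stitching of tile predictions.

Whole-slide images are far too large to feed to a convolutional network
directly, so each slide/annotation pair is converted to a mosaic of
overlapping fixed-size tiles.  Tile dimensions must be divisible by the
network's total scaling factor S = 2**n (n pooling/striding operations)
so feature maps divide evenly at every level.  After inference, tile
probability maps are stitched back by averaging overlaps and taking the
per-pixel argmax.

Tiles whose annotation is more than 90% "ignore" carry essentially no
supervisory signal and are discarded; tiles at or below that fraction
are kept (tiles with at most 10% ignore are additionally flagged as
"clean").  Coordinates are 0-based pixels, origin at the top-left,
x = column and y = row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classes import CLASS_ORDER, CLASS_INDEX, DEFAULT_MICRONS_PER_PX
from . import raster_io

__all__ = [
    "AnnotationMap",
    "TileRecord",
    "make_mosaic",
    "ignore_fraction",
    "filter_tile",
    "stitch_predictions",
    "DEFAULT_TILE_SIZE",
    "DEFAULT_SCALING",
]

#: Tile edge in pixels (384 px = 175 µm at 2.2 px/µm).
DEFAULT_TILE_SIZE = 384
#: Total down-scaling factor S = 2**n the tile size must divide by.
DEFAULT_SCALING = 16

IGNORE_DISCARD_FRACTION = 0.90
CLEAN_FRACTION = 0.10


@dataclass
class AnnotationMap:
    """Integer class-label raster paired with a slide."""

    labels: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER
    microns_per_px: float = DEFAULT_MICRONS_PER_PX

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("annotation labels must be a 2-D raster")
        if self.labels.max(initial=0) >= len(self.class_order):
            raise ValueError("label value outside class_order")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def ignore_index(self) -> int:
        return self.class_order.index("ignore")

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=len(self.class_order))
        return {name: int(c) for name, c in zip(self.class_order, counts)}

    def save(self, path: str | Path) -> None:
        raster_io.save_indexed(path, self.labels, self.class_order)

    @classmethod
    def load(cls, path: str | Path,
             microns_per_px: float = DEFAULT_MICRONS_PER_PX) -> "AnnotationMap":
        return cls(raster_io.load_indexed(path), CLASS_ORDER, microns_per_px)


@dataclass
class TileRecord:
    """A paired input/target tile with its position in the source slide."""

    input_tile: np.ndarray
    target_tile: np.ndarray
    origin: tuple[int, int]  # (x, y) pixel offset
    slide_id: str = ""
    clean: bool = field(default=False)  # ignore fraction <= 10%

    @property
    def tile_size(self) -> int:
        return self.target_tile.shape[0]


def _axis_offsets(extent: int, tile: int, stride: int) -> list[int]:
    """Tile offsets along one axis; the last tile is back-shifted in-bounds."""
    offsets = list(range(0, extent - tile + 1, stride))
    if offsets[-1] != extent - tile:
        offsets.append(extent - tile)
    return offsets


def make_mosaic(
    slide: np.ndarray,
    annotation: AnnotationMap,
    tile_size: int = DEFAULT_TILE_SIZE,
    stride: int | None = None,
    scaling: int = DEFAULT_SCALING,
    slide_id: str = "",
) -> list[TileRecord]:
    """Cut a slide/annotation pair into overlapping tiles covering every pixel.

    ``stride`` defaults to half the tile size (50% overlap).  Raises if
    the tile size is not divisible by the network scaling factor or the
    slide is smaller than one tile.
    """
    slide = np.asarray(slide)
    if slide.shape[:2] != annotation.shape:
        raise ValueError("slide and annotation dimensions differ")
    if tile_size % scaling != 0:
        raise ValueError(
            f"tile_size {tile_size} is not divisible by the scaling factor S={scaling}"
        )
    h, w = annotation.shape
    if h < tile_size or w < tile_size:
        raise ValueError(f"slide {w}x{h} is smaller than one {tile_size}px tile")
    if stride is None:
        stride = tile_size // 2
    if not 0 < stride <= tile_size:
        raise ValueError("stride must be in (0, tile_size]")

    records = []
    for y in _axis_offsets(h, tile_size, stride):
        for x in _axis_offsets(w, tile_size, stride):
            target = annotation.labels[y : y + tile_size, x : x + tile_size]
            frac = ignore_fraction(target, annotation.ignore_index)
            records.append(
                TileRecord(
                    input_tile=slide[y : y + tile_size, x : x + tile_size],
                    target_tile=target,
                    origin=(x, y),
                    slide_id=slide_id,
                    clean=frac <= CLEAN_FRACTION,
                )
            )
    return records


def ignore_fraction(target_tile: np.ndarray,
                    ignore_index: int = CLASS_INDEX["ignore"]) -> float:
    target_tile = np.asarray(target_tile)
    return float(np.mean(target_tile == ignore_index))


def filter_tile(target_tile: np.ndarray,
                ignore_index: int = CLASS_INDEX["ignore"]) -> bool:
    """Keep/discard rule: tiles with more than 90% ignore pixels are discarded."""
    return ignore_fraction(target_tile, ignore_index) <= IGNORE_DISCARD_FRACTION


def filter_mosaic(records: Iterable[TileRecord],
                  ignore_index: int = CLASS_INDEX["ignore"]) -> list[TileRecord]:
    return [r for r in records if filter_tile(r.target_tile, ignore_index)]


def stitch_predictions(
    tiles: Sequence[tuple[tuple[int, int], np.ndarray]],
    slide_shape: tuple[int, int],
    class_order: tuple[str, ...] = CLASS_ORDER,
    microns_per_px: float = DEFAULT_MICRONS_PER_PX,
    return_probabilities: bool = False,
):
    """Stitch per-tile class-probability maps into a whole-slide map.

    ``tiles`` is a sequence of ``((x, y), probs)`` with ``probs`` of
    shape (tile, tile, n_classes).  Overlapping probabilities are
    averaged per pixel, then argmaxed over classes.  Raises if any slide
    pixel is not covered by at least one tile.
    """
    h, w = slide_shape
    n_classes = len(class_order)
    acc = np.zeros((h, w, n_classes), dtype=np.float64)
    cover = np.zeros((h, w), dtype=np.int32)
    for (x, y), probs in tiles:
        probs = np.asarray(probs, dtype=np.float64)
        th, tw = probs.shape[:2]
        if y + th > h or x + tw > w or x < 0 or y < 0:
            raise ValueError(f"tile at ({x}, {y}) extends outside the slide")
        acc[y : y + th, x : x + tw] += probs
        cover[y : y + th, x : x + tw] += 1
    if np.any(cover == 0):
        ys, xs = np.nonzero(cover == 0)
        raise ValueError(
            f"{len(ys)} slide pixels not covered by any tile "
            f"(first gap at x={xs[0]}, y={ys[0]})"
        )
    mean = acc / cover[..., None]
    labels = np.argmax(mean, axis=-1).astype(np.uint8)
    ann = AnnotationMap(labels, class_order, microns_per_px)
    if return_probabilities:
        return ann, mean
    return ann


def mosaic_manifest(records: Sequence[TileRecord]) -> pd.DataFrame:
    """Tabular manifest of a mosaic (slide id, origin, ignore stats)."""
    return pd.DataFrame(
        {
            "slide_id": [r.slide_id for r in records],
            "x": [r.origin[0] for r in records],
            "y": [r.origin[1] for r in records],
            "tile_size": [r.tile_size for r in records],
            "ignore_fraction": [ignore_fraction(r.target_tile) for r in records],
            "clean": [r.clean for r in records],
        }
    )


def write_tile_pairs(records: Sequence[TileRecord], out_dir: str | Path) -> pd.DataFrame:
    """Write paired input (24-bit PNG) / target (indexed PNG) tiles.

    Filenames encode the slide id and tile origin; returns the manifest
    with file paths added (also saved as ``manifest.csv``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = mosaic_manifest(records)
    inputs, targets = [], []
    for r in records:
        stem = f"{r.slide_id or 'slide'}_x{r.origin[0]}_y{r.origin[1]}"
        ipath, tpath = out / f"{stem}_input.png", out / f"{stem}_target.png"
        raster_io.save_rgb(ipath, r.input_tile)
        raster_io.save_indexed(tpath, r.target_tile)
        inputs.append(ipath.name)
        targets.append(tpath.name)
    manifest["input_png"] = inputs
    manifest["target_png"] = targets
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
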