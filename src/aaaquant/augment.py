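"""Dataset normalization and input/target-consistent augmentation.

Two families of transforms are distinguished:

* *arithmetic* (additive shift, multiplicative gain, pixel dropout) —
  applied to the input image only, on a [0, 1] intensity scale with
  clipping;
* *geometric* (flips, rotation, scaling, elastic deformation) — applied
  identically to input and target; the target is warped with
  nearest-neighbor interpolation so no new labels are invented, and all
  warps use reflective edge handling to preserve continuity.

Per sample, each transform in the menu is independently included with
probability 0.5 ("one or several" transforms on average); parameter
ranges follow the training recipe: additive in [-0.07, 0.07], gain in
[0.8, 1.2], dropout fraction in [0.10, 0.50], rotation in [-90, 90]
degrees, scale in [0.8, 1.2], elastic sigma 40.0 with alpha in
[50, 200].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml
from scipy import ndimage
from skimage import transform as sktransform

from .tiling import TileRecord

__all__ = [
    "NormalizationStats",
    "AugmentationPlan",
    "fit_normalization",
    "apply_augmentation",
    "normalize",
]

ELASTIC_SIGMA = 40.0


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean and std over every pixel of a tile dataset."""

    per_channel_mean: tuple[float, float, float]
    per_channel_std: tuple[float, float, float]
    computed_over: str = ""

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.per_channel_std):
            raise ValueError("per-channel std must be > 0 (degenerate dataset)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "per_channel_mean": [float(m) for m in self.per_channel_mean],
                    "per_channel_std": [float(s) for s in self.per_channel_std],
                    "computed_over": self.computed_over,
                }
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NormalizationStats":
        d = yaml.safe_load(Path(path).read_text())
        return cls(tuple(d["per_channel_mean"]), tuple(d["per_channel_std"]),
                   d.get("computed_over", ""))


def fit_normalization(tiles: Iterable[np.ndarray], dataset_id: str = "") -> NormalizationStats:
    """Streaming per-channel mean/std over all pixels of all tiles.

    Accepts uint8 (rescaled to [0, 1]) or float tiles.  Uses running
    sums of x and x**2; numerically adequate for unit-scale image data.
    """
    n = 0
    s = np.zeros(3, dtype=np.float64)
    s2 = np.zeros(3, dtype=np.float64)
    for tile in tiles:
        x = _to_unit(tile).reshape(-1, 3).astype(np.float64)
        n += x.shape[0]
        s += x.sum(axis=0)
        s2 += (x * x).sum(axis=0)
    if n == 0:
        raise ValueError("cannot fit normalization on an empty dataset")
    mean = s / n
    var = np.maximum(s2 / n - mean * mean, 0.0)
    return NormalizationStats(
        tuple(float(m) for m in mean),
        tuple(float(v) for v in np.sqrt(var)),
        dataset_id,
    )


def normalize(tile: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    x = _to_unit(tile)
    return (x - np.asarray(stats.per_channel_mean)) / np.asarray(stats.per_channel_std)


def _to_unit(tile: np.ndarray) -> np.ndarray:
    tile = np.asarray(tile)
    if tile.dtype == np.uint8:
        return tile.astype(np.float64) / 255.0
    return tile.astype(np.float64)


@dataclass(frozen=True)
class AugmentationPlan:
    """A concrete sampled set of transforms with their parameters.

    ``None`` means the transform is not applied.  Use :meth:`sample` to
    draw a plan; construct directly for deterministic single-transform
    tests.
    """

    additive: float | None = None          # arithmetic, input only
    multiplicative: float | None = None    # arithmetic, input only
    dropout_fraction: float | None = None  # arithmetic, input only
    flip_ud: bool = False                  # geometric, pair-applied
    flip_lr: bool = False
    rotation_deg: float | None = None
    scale: float | None = None
    elastic_alpha: float | None = None     # sigma fixed at ELASTIC_SIGMA
    seed: int = 0                          # drives dropout mask + elastic field

    _RANGES = {
        "additive": (-0.07, 0.07),
        "multiplicative": (0.8, 1.2),
        "dropout_fraction": (0.10, 0.50),
        "rotation_deg": (-90.0, 90.0),
        "scale": (0.8, 1.2),
        "elastic_alpha": (50.0, 200.0),
    }

    def __post_init__(self) -> None:
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if v is not None and not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def sample(cls, rng: np.random.Generator, p_include: float = 0.5) -> "AugmentationPlan":
        def maybe(lo: float, hi: float) -> float | None:
            return float(rng.uniform(lo, hi)) if rng.random() < p_include else None

        return cls(
            additive=maybe(*cls._RANGES["additive"]),
            multiplicative=maybe(*cls._RANGES["multiplicative"]),
            dropout_fraction=maybe(*cls._RANGES["dropout_fraction"]),
            flip_ud=bool(rng.random() < p_include),
            flip_lr=bool(rng.random() < p_include),
            rotation_deg=maybe(*cls._RANGES["rotation_deg"]),
            scale=maybe(*cls._RANGES["scale"]),
            elastic_alpha=maybe(*cls._RANGES["elastic_alpha"]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )


def _warp_pair(inp: np.ndarray, tgt: np.ndarray, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resample input (bilinear) and target (nearest) at given coordinates."""
    out_i = np.stack(
        [
            ndimage.map_coordinates(inp[..., c], coords, order=1, mode="reflect")
            for c in range(inp.shape[-1])
        ],
        axis=-1,
    )
    out_t = ndimage.map_coordinates(tgt, coords, order=0, mode="reflect")
    return out_i, out_t


def apply_augmentation(pair: TileRecord, plan: AugmentationPlan) -> TileRecord:
    """Apply a sampled plan to a tile pair.

    Geometric transforms are applied first (identically to both
    rasters), then the arithmetic transforms touch the input only.  The
    returned input is float in [0, 1]; the target keeps its dtype.
    """
    inp = _to_unit(pair.input_tile)
    tgt = np.asarray(pair.target_tile)
    rng = np.random.default_rng(plan.seed)

    # --- geometric (pair-applied) ---
    if plan.flip_ud:
        inp, tgt = inp[::-1], tgt[::-1]
    if plan.flip_lr:
        inp, tgt = inp[:, ::-1], tgt[:, ::-1]
    if plan.rotation_deg is not None:
        inp = sktransform.rotate(inp, plan.rotation_deg, mode="reflect", order=1,
                                 preserve_range=True)
        tgt = sktransform.rotate(tgt.astype(float), plan.rotation_deg, mode="reflect",
                                 order=0, preserve_range=True).astype(pair.target_tile.dtype)
    if plan.scale is not None:
        h, w = tgt.shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        # inverse map of scaling about the tile center
        coords = np.stack([(yy - cy) / plan.scale + cy, (xx - cx) / plan.scale + cx])
        inp, tgt = _warp_pair(inp, tgt, coords)
    if plan.elastic_alpha is not None:
        h, w = tgt.shape
        # Simard-style field: uniform noise, Gaussian-smoothed, scaled
        dy = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), ELASTIC_SIGMA) * plan.elastic_alpha
        dx = ndimage.gaussian_filter(rng.uniform(-1, 1, (h, w)), ELASTIC_SIGMA) * plan.elastic_alpha
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        inp, tgt = _warp_pair(inp, tgt, np.stack([yy + dy, xx + dx]))

    # --- arithmetic (input only) ---
    if plan.additive is not None:
        inp = np.clip(inp + plan.additive, 0.0, 1.0)
    if plan.multiplicative is not None:
        inp = np.clip(inp * plan.multiplicative, 0.0, 1.0)
    if plan.dropout_fraction is not None:
        n_pix = tgt.size
        k = int(round(plan.dropout_fraction * n_pix))
        flat = rng.choice(n_pix, size=k, replace=False)
        inp = inp.reshape(-1, 3).copy()
        inp[flat] = 0.0  # dropped pixels become black
        inp = inp.reshape(*tgt.shape, 3)

    return TileRecord(
        input_tile=np.ascontiguousarray(inp),
        target_tile=np.ascontiguousarray(tgt),
        origin=pair.origin,
        slide_id=pair.slide_id,
        clean=pair.clean,
    )
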