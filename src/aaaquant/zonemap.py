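"""Per-class region masks from a stitched prediction, with transfer QC.

A whole-slide segmentation is split into one binary mask per class
(zone 1, zone 2, thrombus, background); masks are mutually exclusive
and, together with the ignore pixels, partition the slide.  Masks can
be exported/imported losslessly as indexed PNG.

Masks defined on an elastin-stained section are applied to serial
immunostained sections by identity placement — serial 5 µm sections are
nominally congruent, but in practice are often displaced or distorted
on the glass, so :func:`apply_masks` computes a quantitative overlap QC
score (the fraction of detected tissue pixels falling inside the union
of the tissue-class masks) and gates PASS/FAIL on it instead of relying
on visual triage.  Landmark registration is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classes import CLASS_INDEX, CLASS_ORDER, DEFAULT_MICRONS_PER_PX, TISSUE_CLASSES
from .tiling import AnnotationMap
from . import raster_io

__all__ = ["ZoneMaskSet", "QCResult", "masks_from_prediction", "apply_masks"]

MASK_CLASSES: tuple[str, ...] = ("zone1", "zone2", "thrombus", "background")


@dataclass
class ZoneMaskSet:
    """One binary mask per (non-ignore) class, plus provenance."""

    masks: dict[str, np.ndarray]
    microns_per_px: float = DEFAULT_MICRONS_PER_PX
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("masks have inconsistent shapes")
        stack = np.stack([self.masks[c] for c in self.masks])
        if np.any(stack.sum(axis=0) > 1):
            raise ValueError("masks are not mutually exclusive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.masks.values())).shape

    def area_px(self, name: str) -> int:
        return int(self.masks[name].sum())

    def area_mm2(self, name: str) -> float:
        """Mask area in mm^2: pixels * (um/px)^2 / 1e6."""
        return self.area_px(name) * self.microns_per_px ** 2 / 1e6

    @property
    def tissue_union(self) -> np.ndarray:
        return np.logical_or.reduce(
            [self.masks[c] for c in TISSUE_CLASSES if c in self.masks]
        )

    def to_annotation(self) -> AnnotationMap:
        """Combined indexed map; pixels in no mask become ignore."""
        labels = np.full(self.shape, CLASS_INDEX["ignore"], dtype=np.uint8)
        for name, mask in self.masks.items():
            labels[mask] = CLASS_INDEX[name]
        return AnnotationMap(labels, CLASS_ORDER, self.microns_per_px)

    def save(self, out_dir: str | Path, prefix: str = "mask") -> dict[str, Path]:
        """Per-class binary PNGs plus a combined indexed PNG."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for name, mask in self.masks.items():
            p = out / f"{prefix}_{name}.png"
            raster_io.save_rgb(p, np.repeat(mask[..., None].astype(np.uint8) * 255, 3, axis=-1))
            paths[name] = p
        combined = out / f"{prefix}_combined.png"
        self.to_annotation().save(combined)
        paths["combined"] = combined
        return paths

    @classmethod
    def load(cls, combined_png: str | Path,
             microns_per_px: float = DEFAULT_MICRONS_PER_PX) -> "ZoneMaskSet":
        ann = AnnotationMap.load(combined_png, microns_per_px)
        return masks_from_prediction(ann)


def masks_from_prediction(pred: AnnotationMap) -> ZoneMaskSet:
    """Binary per-class masks from a predicted (or true) annotation map."""
    masks = {
        name: pred.labels == CLASS_INDEX[name]
        for name in MASK_CLASSES
        if name in pred.class_order
    }
    return ZoneMaskSet(masks, pred.microns_per_px,
                       provenance={"class_order": list(pred.class_order)})


@dataclass(frozen=True)
class QCResult:
    score: float
    passed: bool
    reason: str = ""
    tissue_px: int = 0


def detect_tissue(target_slide: np.ndarray, luminance_threshold: float = 0.9) -> np.ndarray:
    """Tissue pixels: luminance below a fraction of the estimated white level."""
    rgb = np.asarray(target_slide, dtype=float)
    lum = rgb @ np.array([0.2126, 0.7152, 0.0722])
    white = np.percentile(lum, 99)
    if white <= 0:
        return np.zeros(lum.shape, dtype=bool)
    return lum < luminance_threshold * white


def apply_masks(
    masks: ZoneMaskSet,
    target_slide: np.ndarray,
    gate: float = 0.8,
    luminance_threshold: float = 0.9,
    dim_tolerance_px: int = 0,
) -> tuple[QCResult, ZoneMaskSet]:
    """Transfer masks to a serial-section image with an overlap QC gate.

    Placement is identity (no registration).  The QC score is the
    fraction of detected tissue pixels in the target that fall inside
    the union of the tissue-class masks; scores below ``gate`` FAIL.
    A dimension mismatch beyond ``dim_tolerance_px`` fails outright.
    """
    target_slide = np.asarray(target_slide)
    th, tw = target_slide.shape[:2]
    mh, mw = masks.shape
    if abs(th - mh) > dim_tolerance_px or abs(tw - mw) > dim_tolerance_px:
        return (
            QCResult(0.0, False,
                     f"displaced/resized: target {tw}x{th} vs masks {mw}x{mh}"),
            masks,
        )
    h, w = min(th, mh), min(tw, mw)
    tissue = detect_tissue(target_slide[:h, :w], luminance_threshold)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        return QCResult(0.0, False, "no tissue detected in target"), masks
    inside = np.logical_and(tissue, masks.tissue_union[:h, :w])
    score = float(inside.sum() / n_tissue)
    passed = score >= gate
    return QCResult(score, passed, "" if passed else f"overlap {score:.3f} < gate {gate}",
                    n_tissue), masks
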