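"""Synthetic AAA slides with exact ground truth.

Real AAA whole-slide images cannot be redistributed, so this module
fabricates the three inputs the pipeline consumes, each with a fully
known truth record:

* an elastin-stained ("Weigert-like") slide whose wall architecture is a
  thrombus core, a vascular-wall ring (zone 1) and a loose perivascular
  ring (zone 2) on an empty background, with elastin and collagen fibers
  rendered at requested per-zone area fractions;
* the matching annotation map, including an "ignore" band along zone
  borders (mimicking annotation uncertainty);
* an immunostained (hematoxylin + DAB) serial section with planted,
  non-overlapping nuclei at known per-zone counts and positivity.

All color is produced through the forward Beer-Lambert model in
:mod:`aaaquant.stains`, so stain unmixing downstream is an exact inverse
at zero noise.  Everything is deterministic given the ``SlideSpec`` seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .classes import (
    CLASS_ORDER,
    CLASS_INDEX,
    DEFAULT_MICRONS_PER_PX,
    TISSUE_CLASSES,
)
from .stains import StainModel, hdab_model, mix, weigert_model
from .tiling import AnnotationMap

__all__ = [
    "ZoneGeometry",
    "SlideSpec",
    "PlantedCell",
    "SyntheticTruth",
    "generate_annotation",
    "generate_weigert_slide",
    "generate_ihc_slide",
]


@dataclass(frozen=True)
class ZoneGeometry:
    """Parametric wall geometry.

    ``concentric`` (default) lays out a thrombus core and two annular
    zones with a seeded angular wobble on each boundary, mimicking an
    annular biopsy cross-section.  ``blobs`` places irregular elliptical
    regions instead, for slides with non-annular morphology.  Radii are
    fractions of half the shorter image side.
    """

    mode: Literal["concentric", "blobs"] = "concentric"
    thrombus_radius: float = 0.30
    zone1_radius: float = 0.60
    zone2_radius: float = 0.92
    wobble: float = 0.06  # relative amplitude of the boundary perturbation

    def __post_init__(self) -> None:
        if not 0.0 <= self.thrombus_radius < self.zone1_radius < self.zone2_radius <= 1.0:
            raise ValueError("zone radii must satisfy 0 <= thrombus < zone1 <= zone2 <= 1")


@dataclass(frozen=True)
class SlideSpec:
    """Everything needed to synthesize one slide deterministically."""

    width_px: int = 768
    height_px: int = 768
    microns_per_px: float = DEFAULT_MICRONS_PER_PX
    zone_geometry: ZoneGeometry = field(default_factory=ZoneGeometry)
    #: per-zone target area fractions, e.g. {"zone1": {"elastin": .25, "collagen": .3}}
    fiber_fractions: dict = field(default_factory=dict)
    seed: int = 0
    noise_sigma: float = 0.02  # RGB noise std as a fraction of dynamic range
    ignore_border_px: int = 4  # half-width of the ignore band at zone borders
    nucleus_diameter_um: float = 8.0
    cytoplasm_ring_um: float = 3.0

    def __post_init__(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("slide must be at least 64x64 px")
        if self.microns_per_px <= 0:
            raise ValueError("microns_per_px must be positive")
        for zone, fracs in self.fiber_fractions.items():
            if zone not in TISSUE_CLASSES:
                raise ValueError(f"fiber fractions given for non-tissue zone {zone!r}")
            total = sum(fracs.values())
            if not 0.0 <= total <= 1.0:
                raise ValueError(f"fiber fractions for {zone} sum to {total}, outside [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        d = {
            "width_px": self.width_px,
            "height_px": self.height_px,
            "microns_per_px": self.microns_per_px,
            "zone_geometry": {
                "mode": self.zone_geometry.mode,
                "thrombus_radius": self.zone_geometry.thrombus_radius,
                "zone1_radius": self.zone_geometry.zone1_radius,
                "zone2_radius": self.zone_geometry.zone2_radius,
                "wobble": self.zone_geometry.wobble,
            },
            "fiber_fractions": self.fiber_fractions,
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "ignore_border_px": self.ignore_border_px,
            "nucleus_diameter_um": self.nucleus_diameter_um,
            "cytoplasm_ring_um": self.cytoplasm_ring_um,
        }
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SlideSpec":
        d = yaml.safe_load(Path(path).read_text())
        geom = d.pop("zone_geometry", {})
        return cls(zone_geometry=ZoneGeometry(**geom), **d)


@dataclass
class PlantedCell:
    centroid: tuple[float, float]  # (x, y) pixels
    zone: str
    positive: bool


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated slide."""

    annotation: AnnotationMap
    #: zone labels before the ignore band was painted over borders
    zone_labels: np.ndarray
    planted_cells: list[PlantedCell] = field(default_factory=list)
    per_zone_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    per_zone_fiber_area: dict[str, tuple[int, int]] = field(default_factory=dict)

    def cells_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "x_px": [c.centroid[0] for c in self.planted_cells],
                "y_px": [c.centroid[1] for c in self.planted_cells],
                "zone": [c.zone for c in self.planted_cells],
                "positive": [c.positive for c in self.planted_cells],
            }
        ).to_csv(path, index=False)


def _zone_labels(spec: SlideSpec, rng: np.random.Generator) -> np.ndarray:
    """Zone layout (no ignore band): values index CLASS_ORDER."""
    h, w = spec.height_px, spec.width_px
    geom = spec.zone_geometry
    labels = np.full((h, w), CLASS_INDEX["background"], dtype=np.uint8)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    half = min(h, w) / 2.0

    if geom.mode == "concentric":
        rr = np.hypot(yy - cy, xx - cx) / half
        theta = np.arctan2(yy - cy, xx - cx)

        def boundary(base: float) -> np.ndarray:
            # seeded low-order angular wobble, distinct per boundary
            amp = geom.wobble * base
            phases = rng.uniform(0, 2 * np.pi, size=3)
            weights = rng.uniform(0.3, 1.0, size=3)
            wob = sum(
                wgt * np.sin(k * theta + ph)
                for k, (ph, wgt) in enumerate(zip(phases, weights), start=2)
            )
            return base + amp * wob / np.sum(np.abs(weights))

        b_thr = boundary(geom.thrombus_radius)
        b_z1 = boundary(geom.zone1_radius)
        b_z2 = boundary(geom.zone2_radius)
        labels[rr < b_z2] = CLASS_INDEX["zone2"]
        labels[rr < b_z1] = CLASS_INDEX["zone1"]
        labels[rr < b_thr] = CLASS_INDEX["thrombus"]
    elif geom.mode == "blobs":
        def ellipse(cxf, cyf, axf, ayf, angle) -> np.ndarray:
            ca, sa = np.cos(angle), np.sin(angle)
            dx, dy = xx - cxf * w, yy - cyf * h
            u = (ca * dx + sa * dy) / (axf * half)
            v = (-sa * dx + ca * dy) / (ayf * half)
            return u * u + v * v < 1.0

        labels[ellipse(0.5 + rng.uniform(-0.05, 0.05), 0.5 + rng.uniform(-0.05, 0.05),
                       geom.zone2_radius, geom.zone2_radius * rng.uniform(0.7, 1.0),
                       rng.uniform(0, np.pi))] = CLASS_INDEX["zone2"]
        labels[ellipse(0.5 + rng.uniform(-0.08, 0.08), 0.5 + rng.uniform(-0.08, 0.08),
                       geom.zone1_radius, geom.zone1_radius * rng.uniform(0.6, 0.9),
                       rng.uniform(0, np.pi))] = CLASS_INDEX["zone1"]
        labels[ellipse(0.5 + rng.uniform(-0.1, 0.1), 0.5 + rng.uniform(-0.1, 0.1),
                       geom.thrombus_radius, geom.thrombus_radius * rng.uniform(0.5, 0.9),
                       rng.uniform(0, np.pi))] = CLASS_INDEX["thrombus"]
    else:  # pragma: no cover - guarded by ZoneGeometry literal type
        raise ValueError(f"unknown geometry mode {geom.mode!r}")
    return labels


def _with_ignore_band(zone_labels: np.ndarray, border_px: int) -> np.ndarray:
    """Paint an ignore band over inter-class borders."""
    labels = zone_labels.copy()
    if border_px <= 0:
        return labels
    edges = np.zeros(labels.shape, dtype=bool)
    edges[:-1, :] |= labels[:-1, :] != labels[1:, :]
    edges[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    band = ndimage.binary_dilation(edges, ndimage.generate_binary_structure(2, 2),
                                   iterations=border_px)
    labels[band] = CLASS_INDEX["ignore"]
    return labels


def generate_annotation(spec: SlideSpec) -> tuple[AnnotationMap, np.ndarray]:
    """Annotation map (with ignore band) and raw zone labels for a spec."""
    rng = np.random.default_rng(spec.seed)
    zones = _zone_labels(spec, rng)
    ann = AnnotationMap(_with_ignore_band(zones, spec.ignore_border_px),
                        CLASS_ORDER, spec.microns_per_px)
    return ann, zones


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.min()) / max(float(np.ptp(f)), 1e-12)


def _top_k_mask(score: np.ndarray, eligible: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k highest-scoring eligible pixels (exact count)."""
    mask = np.zeros(score.shape, dtype=bool)
    if k <= 0:
        return mask
    idx = np.flatnonzero(eligible)
    order = np.argsort(score.ravel()[idx], kind="stable")[::-1]
    mask.ravel()[idx[order[:k]]] = True
    return mask


# Per-zone background-stain base concentration and texture scale: these
# give each zone a distinct mean color and texture so zones are visually
# and statistically separable.
_ZONE_TINT = {"zone1": 0.55, "zone2": 0.22, "thrombus": 0.85}
_ZONE_TEXTURE_SIGMA = {"zone1": 3.0, "zone2": 8.0, "thrombus": 1.5}


def generate_weigert_slide(spec: SlideSpec) -> tuple[np.ndarray, SyntheticTruth]:
    """Render an elastin/collagen-stained slide with known fiber fractions.

    Fiber pixels are chosen as exact counts (``round(fraction * zone
    area)``) from a smoothed random field, so the rendered per-zone
    fractions match the request to sub-pixel accuracy before noise.
    Returns the uint8 RGB raster and the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    zones = _zone_labels(spec, rng)
    ann = AnnotationMap(_with_ignore_band(zones, spec.ignore_border_px),
                        CLASS_ORDER, spec.microns_per_px)
    h, w = zones.shape
    model = weigert_model()
    conc = np.zeros((h, w, 3))  # (elastin, collagen, background) concentrations

    # faint neutral tint outside the tissue
    conc[..., 2] = 0.02
    fiber_area: dict[str, tuple[int, int]] = {}
    for zone in TISSUE_CLASSES:
        zmask = zones == CLASS_INDEX[zone]
        n_zone = int(zmask.sum())
        fracs = spec.fiber_fractions.get(zone, {})
        k_e = int(round(fracs.get("elastin", 0.0) * n_zone))
        k_c = int(round(fracs.get("collagen", 0.0) * n_zone))
        if n_zone == 0:
            if k_e or k_c:
                raise ValueError(
                    f"geometry renders no pixels for {zone}; cannot place requested fibers"
                )
            fiber_area[zone] = (0, 0)
            continue
        # zone-specific background texture
        tex = _smooth_field(rng, (h, w), _ZONE_TEXTURE_SIGMA[zone])
        conc[..., 2][zmask] = _ZONE_TINT[zone] * (0.75 + 0.5 * tex[zmask])
        if zone == "zone2":
            # adipocyte-like clear holes for texture
            holes = _smooth_field(rng, (h, w), 6.0) > 0.75
            conc[..., 2][zmask & holes] = 0.03
        # fibrous structures: ranked smooth fields give clumped fibers
        # at exact pixel counts
        e_mask = _top_k_mask(_smooth_field(rng, (h, w), 1.5), zmask, k_e)
        c_mask = _top_k_mask(_smooth_field(rng, (h, w), 2.5), zmask & ~e_mask, k_c)
        conc[..., 0][e_mask] = 1.1
        conc[..., 2][e_mask] *= 0.2
        conc[..., 1][c_mask] = 0.9
        conc[..., 2][c_mask] *= 0.3
        fiber_area[zone] = (k_e, k_c)

    rgb = mix(conc, model)
    if spec.noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sigma * 255.0, rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    truth = SyntheticTruth(annotation=ann, zone_labels=zones,
                           per_zone_fiber_area=fiber_area)
    return rgb, truth


def _place_cells(
    rng: np.random.Generator,
    allowed: np.ndarray,
    n: int,
    min_dist: float,
) -> list[tuple[int, int]]:
    """Place n centers (x, y) inside ``allowed`` at pairwise distance >= min_dist.

    Candidate sites come from a randomly shifted and rotated hexagonal
    lattice with small jitter, so the spacing guarantee holds by
    construction and infeasible densities are detected exactly (fewer
    eligible sites than requested cells).
    """
    if n == 0:
        return []
    if not allowed.any():
        raise ValueError("no eligible pixels to place cells in this zone")
    h, w = allowed.shape
    s = min_dist * 1.08
    phi = rng.uniform(0, 2 * np.pi)
    ox, oy = rng.uniform(0, s, size=2)
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    diag = float(np.hypot(h, w))
    i = np.arange(-int(diag / (s * np.sqrt(3) / 2)) - 2, int(diag / (s * np.sqrt(3) / 2)) + 3)
    j = np.arange(-int(diag / s) - 2, int(diag / s) + 3)
    jj, ii = np.meshgrid(j, i)
    lx = jj * s + (ii % 2) * s / 2 + ox
    ly = ii * s * np.sqrt(3) / 2 + oy
    x = cos_p * lx - sin_p * ly + w / 2
    y = sin_p * lx + cos_p * ly + h / 2
    # jitter small enough to preserve the min-distance guarantee
    x = x + rng.uniform(-0.025 * s, 0.025 * s, x.shape)
    y = y + rng.uniform(-0.025 * s, 0.025 * s, y.shape)
    xi = np.round(x.ravel()).astype(int)
    yi = np.round(y.ravel()).astype(int)
    inb = (xi >= 0) & (xi < w) & (yi >= 0) & (yi < h)
    xi, yi = xi[inb], yi[inb]
    ok = allowed[yi, xi]
    sites = list(zip(xi[ok].tolist(), yi[ok].tolist()))
    if len(sites) < n:
        raise ValueError(
            f"cell density too high: zone fits at most {len(sites)} "
            f"non-overlapping nuclei, {n} requested"
        )
    order = rng.permutation(len(sites))[:n]
    return [sites[k] for k in order]


def generate_ihc_slide(
    spec: SlideSpec,
    cells_per_zone: dict[str, int],
    positive_fraction_per_zone: dict[str, float],
    stain: StainModel | None = None,
    dab_compartment: Literal["cell", "cytoplasm"] = "cell",
    hematoxylin_od: float = 0.8,
    dab_od: float = 0.6,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Render a hematoxylin+DAB serial section with planted cells.

    Every cell is a hematoxylin-dark nuclear disk; positive cells carry
    DAB either over the whole cell (nucleus + cytoplasm ring) or over
    the cytoplasm ring only.  Per-zone positive counts are exact:
    ``round(fraction * n)`` cells are flagged positive.
    """
    stain = stain or hdab_model()
    rng = np.random.default_rng(spec.seed)
    zones = _zone_labels(spec, rng)
    ann = AnnotationMap(_with_ignore_band(zones, spec.ignore_border_px),
                        CLASS_ORDER, spec.microns_per_px)
    h, w = zones.shape
    r_px = 0.5 * spec.nucleus_diameter_um / spec.microns_per_px
    ring_px = spec.cytoplasm_ring_um / spec.microns_per_px

    conc = np.zeros((h, w, 3))  # (hematoxylin, dab, residual)
    tissue_tint = {"zone1": 0.10, "zone2": 0.05, "thrombus": 0.14}
    for zone, tint in tissue_tint.items():
        zmask = zones == CLASS_INDEX[zone]
        if zmask.any():
            conc[..., 0][zmask] = tint * (0.7 + 0.6 * _smooth_field(rng, (h, w), 4.0)[zmask])

    cells: list[PlantedCell] = []
    counts: dict[str, tuple[int, int]] = {}
    # nuclei stay fully inside their zone; the cytoplasm ring may graze
    # the ignore band without affecting the recorded truth
    margin = int(np.ceil(r_px + 2))
    for zone, n in cells_per_zone.items():
        if zone not in CLASS_INDEX:
            raise ValueError(f"unknown zone {zone!r}")
        zmask = zones == CLASS_INDEX[zone]
        allowed = ndimage.binary_erosion(zmask, iterations=margin) if n > 0 else zmask
        centers = _place_cells(rng, allowed, n, min_dist=2 * r_px + ring_px + 2)
        n_pos = int(round(positive_fraction_per_zone.get(zone, 0.0) * n))
        pos_idx = set(rng.choice(n, size=n_pos, replace=False).tolist()) if n_pos else set()
        for i, (x, y) in enumerate(centers):
            positive = i in pos_idx
            cells.append(PlantedCell(centroid=(float(x), float(y)), zone=zone,
                                     positive=positive))
            _stamp_cell(conc, x, y, r_px, ring_px, positive, dab_compartment,
                        hematoxylin_od, dab_od)
        counts[zone] = (n, n_pos)

    rgb = mix(conc, stain)
    if spec.noise_sigma > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sigma * 255.0, rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    truth = SyntheticTruth(annotation=ann, zone_labels=zones, planted_cells=cells,
                           per_zone_counts=counts)
    return rgb, truth


def _stamp_cell(
    conc: np.ndarray,
    x: int,
    y: int,
    r_px: float,
    ring_px: float,
    positive: bool,
    compartment: str,
    hematoxylin_od: float,
    dab_od: float,
) -> None:
    h, w = conc.shape[:2]
    r_out = r_px + ring_px
    x0, x1 = max(0, int(x - r_out - 1)), min(w, int(x + r_out + 2))
    y0, y1 = max(0, int(y - r_out - 1)), min(h, int(y + r_out + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - y, xx - x)
    nucleus = dist <= r_px
    cell = dist <= r_out
    patch = conc[y0:y1, x0:x1]
    patch[..., 0][nucleus] = hematoxylin_od
    if positive:
        target = cell if compartment == "cell" else (cell & ~nucleus)
        patch[..., 1][target] = dab_od


def write_slide_bundle(
    out_dir: str | Path,
    spec: SlideSpec,
    rgb: np.ndarray,
    truth: SyntheticTruth,
    prefix: str = "slide",
) -> dict[str, Path]:
    """Persist a generated slide: image, annotation, truth CSVs, spec YAML."""
    from . import raster_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / f"{prefix}.png",
        "annotation": out / f"{prefix}_annotation.png",
        "spec": out / f"{prefix}_spec.yaml",
    }
    raster_io.save_rgb(paths["image"], rgb)
    truth.annotation.save(paths["annotation"])
    spec.to_yaml(paths["spec"])
    if truth.planted_cells:
        paths["cells"] = out / f"{prefix}_cells.csv"
        truth.cells_to_csv(paths["cells"])
    if truth.per_zone_fiber_area:
        paths["fibers"] = out / f"{prefix}_fibers.csv"
        pd.DataFrame(
            [
                {"zone": z, "elastin_px": e, "collagen_px": c}
                for z, (e, c) in truth.per_zone_fiber_area.items()
            ]
        ).to_csv(paths["fibers"], index=False)
    return paths
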