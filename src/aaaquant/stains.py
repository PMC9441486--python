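"""Optical-density transform, stain models, and color deconvolution.

Brightfield stains absorb light, so pixel intensities combine
multiplicatively (Beer-Lambert): ``I_c = I0_c * 10**(-OD_c)``.  In
optical-density space stains mix *additively*, which makes unmixing a
per-pixel linear solve against a 3x3 matrix of unit stain vectors.

Two stain models are used:

* H-DAB for immunostains: hematoxylin (nuclei, blue) + DAB chromogen
  (antibody binding, brown) + a residual channel.
* A Weigert-mode model whose "stains" are reference colors for elastin
  (dark blue-black), collagen (red counterstain), and the pale tissue
  background.

The synthetic slide generator renders images through :func:`mix`, the
exact forward of :func:`unmix`, so detection on noise-free synthetic
slides is an exact inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainModel",
    "od_transform",
    "od_to_rgb",
    "unmix",
    "mix",
    "hdab_model",
    "weigert_model",
]

_EPS = 1e-6


def _unit_rows(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("stain vector with zero norm")
    return m / norms


@dataclass(frozen=True)
class StainModel:
    """A 3x3 matrix of unit optical-density stain vectors.

    Rows are stains, columns are RGB channels.  ``names`` labels the
    rows (e.g. ``("hematoxylin", "dab", "residual")``).  ``i0`` is the
    white reference intensity per channel on a 0-255 scale.
    """

    matrix: np.ndarray
    names: tuple[str, str, str]
    i0: np.ndarray = field(default_factory=lambda: np.array([255.0, 255.0, 255.0]))

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", _unit_rows(self.matrix))
        object.__setattr__(self, "i0", np.asarray(self.i0, dtype=float))
        if self.matrix.shape != (3, 3):
            raise ValueError("stain matrix must be 3x3")
        if abs(np.linalg.det(self.matrix)) < 1e-8:
            raise ValueError("stain matrix is singular and cannot be inverted")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def index(self, name: str) -> int:
        return self.names.index(name)


def od_transform(rgb: np.ndarray, i0: np.ndarray | float = 255.0) -> np.ndarray:
    """Convert intensities to optical density: ``OD = -log10(I / I0)``.

    Zero intensities are guarded with a small epsilon so the result is
    finite.  For in-range intensities (0 < I <= I0) the OD is
    non-negative; intensities above the white reference map to negative
    OD so the transform stays linear and exactly invertible.
    """
    rgb = np.asarray(rgb, dtype=float)
    i0 = np.asarray(i0, dtype=float)
    return -np.log10(np.maximum(rgb, _EPS) / i0)


def od_to_rgb(od: np.ndarray, i0: np.ndarray | float = 255.0) -> np.ndarray:
    """Inverse of :func:`od_transform` (float result, not quantized)."""
    od = np.asarray(od, dtype=float)
    return np.asarray(i0, dtype=float) * np.power(10.0, -od)


def unmix(od: np.ndarray, stains: StainModel) -> np.ndarray:
    """Color deconvolution: per-pixel stain concentrations from OD.

    ``od`` has shape (..., 3); returns the same shape where the last
    axis indexes stains in ``stains.names`` order.  Remixing the result
    with the stain matrix reconstructs the OD exactly (linear inverse).
    """
    od = np.asarray(od, dtype=float)
    return od @ stains.inverse

def mix(concentrations: np.ndarray, stains: StainModel) -> np.ndarray:
    """Forward stain render: concentrations (..., 3) -> RGB float image."""
    conc = np.asarray(concentrations, dtype=float)
    od = conc @ stains.matrix
    return od_to_rgb(od, stains.i0)


# Ruifrok-Johnston H-DAB unmixing basis (the standard brightfield
# deconvolution vectors for hematoxylin + DAB with an orthogonal
# residual channel).
_HDAB = np.array(
    [
        [0.650, 0.704, 0.286],   # hematoxylin
        [0.268, 0.570, 0.776],   # DAB
        [0.7110, -0.4629, 0.5296],  # residual (cross product, unitized)
    ]
)


def hdab_model(i0: float = 255.0) -> StainModel:
    """Standard H-DAB color-deconvolution stain model."""
    return StainModel(_HDAB, ("hematoxylin", "dab", "residual"), np.full(3, i0))


# Weigert-mode reference colors in OD space.  These are configuration,
# not measured ground truth: elastin fibers appear dark blue-black,
# collagen is counterstained red, and non-fiber tissue is a pale
# pink-gray.  The synthetic generator renders with exactly this basis.
_WEIGERT = np.array(
    [
        [0.55, 0.60, 0.58],  # elastin: near-neutral dark (blue-black)
        [0.25, 0.75, 0.60],  # collagen: absorbs green/blue -> appears red
        [0.40, 0.30, 0.87],  # background tissue: pale warm tint
    ]
)


def weigert_model(i0: float = 255.0) -> StainModel:
    """Reference-color model for elastin / collagen / tissue background."""
    return StainModel(_WEIGERT, ("elastin", "collagen", "background"), np.full(3, i0))
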