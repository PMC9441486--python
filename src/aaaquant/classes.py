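"""Semantic classes and color palette for AAA wall segmentation.

The segmentation model distinguishes five labels: the vascular wall
("zone 1"), loose perivascular tissue ("zone 2"), residual intraluminal
thrombus, annotated background, and an "ignore" label that marks
uncertain zone borders and unannotated surroundings.  The ignore label
is excluded from the training loss and, optionally, from aggregate
metrics.
"""

from __future__ import annotations

# Canonical class order; annotation rasters store these integer indices.
IGNORE = 0
ZONE1 = 1
ZONE2 = 2
THROMBUS = 3
BACKGROUND = 4

CLASS_ORDER: tuple[str, ...] = ("ignore", "zone1", "zone2", "thrombus", "background")
N_CLASSES = len(CLASS_ORDER)

CLASS_INDEX: dict[str, int] = {name: i for i, name in enumerate(CLASS_ORDER)}

# Display palette: zone1 blue, zone2 green, thrombus red, background
# purple, ignore gray.  Used for indexed-PNG annotation maps and overlays.
PALETTE: dict[str, tuple[int, int, int]] = {
    "ignore": (128, 128, 128),
    "zone1": (0, 0, 255),
    "zone2": (0, 255, 0),
    "thrombus": (255, 0, 0),
    "background": (128, 0, 128),
}

# Tissue classes: the union of their masks is what counts as "inside the
# annotated specimen" for QC overlap scoring.
TISSUE_CLASSES: tuple[str, ...] = ("zone1", "zone2", "thrombus")

#: Default image resolution: slides scanned at 2.2 pixels per micron.
DEFAULT_MICRONS_PER_PX = 1.0 / 2.2
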