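import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from aaaquant.synthetic import SlideSpec, generate_ihc_slide, generate_weigert_slide
from aaaquant.tiling import AnnotationMap
from aaaquant.zonemap import masks_from_prediction


@pytest.fixture(scope="session")
def weigert_spec() -> SlideSpec:
    return SlideSpec(
        width_px=512,
        height_px=512,
        seed=7,
        fiber_fractions={
            "zone1": {"elastin": 0.25, "collagen": 0.30},
            "zone2": {"elastin": 0.05, "collagen": 0.40},
        },
    )


@pytest.fixture(scope="session")
def weigert_slide(weigert_spec):
    """A rendered fiber-stained slide with its ground truth."""
    return generate_weigert_slide(weigert_spec)


@pytest.fixture(scope="session")
def ihc_slide(weigert_spec):
    """An immunostained serial section with planted cells (moderate noise)."""
    return generate_ihc_slide(
        weigert_spec,
        cells_per_zone={"zone1": 40, "zone2": 25},
        positive_fraction_per_zone={"zone1": 0.5, "zone2": 0.2},
    )


@pytest.fixture(scope="session")
def truth_masks(weigert_spec, weigert_slide):
    """Zone masks built from the true (pre-ignore) zone labels."""
    _, truth = weigert_slide
    ann = AnnotationMap(truth.zone_labels, microns_per_px=weigert_spec.microns_per_px)
    return masks_from_prediction(ann)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
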