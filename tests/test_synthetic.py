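import numpy as np
import pytest

from aaaquant.classes import CLASS_INDEX, CLASS_ORDER
from aaaquant.stains import hdab_model, od_transform, unmix
from aaaquant.synthetic import (
    SlideSpec,
    ZoneGeometry,
    generate_annotation,
    generate_ihc_slide,
    generate_weigert_slide,
)


class TestSlideSpec:
    def test_fiber_fractions_must_sum_below_one(self):
        with pytest.raises(ValueError, match="sum"):
            SlideSpec(fiber_fractions={"zone1": {"elastin": 0.6, "collagen": 0.6}})

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError, match="radii"):
            ZoneGeometry(thrombus_radius=0.7, zone1_radius=0.5)

    def test_yaml_roundtrip(self, tmp_path, weigert_spec):
        weigert_spec.to_yaml(tmp_path / "spec.yaml")
        loaded = SlideSpec.from_yaml(tmp_path / "spec.yaml")
        assert loaded == weigert_spec


class TestAnnotation:
    def test_all_classes_present_in_concentric_layout(self, weigert_spec):
        ann, zones = generate_annotation(weigert_spec)
        present = set(np.unique(ann.labels))
        assert present == set(range(len(CLASS_ORDER)))

    def test_ignore_band_sits_on_zone_borders(self, weigert_spec):
        ann, zones = generate_annotation(weigert_spec)
        ignore = ann.labels == CLASS_INDEX["ignore"]
        assert ignore.any()
        # away from the band, annotation equals the raw zone layout
        assert np.array_equal(ann.labels[~ignore], zones[~ignore])

    def test_blob_mode_produces_tissue(self):
        spec = SlideSpec(width_px=256, height_px=256, seed=5,
                         zone_geometry=ZoneGeometry(mode="blobs"))
        ann, zones = generate_annotation(spec)
        assert (zones == CLASS_INDEX["zone1"]).sum() > 0


class TestWeigertSlide:
    def test_deterministic_given_seed(self, weigert_spec, weigert_slide):
        rgb, truth = weigert_slide
        rgb2, truth2 = generate_weigert_slide(weigert_spec)
        assert np.array_equal(rgb, rgb2)
        assert np.array_equal(truth.annotation.labels, truth2.annotation.labels)

    def test_different_seeds_differ(self, weigert_spec, weigert_slide):
        rgb, _ = weigert_slide
        other = SlideSpec(**{**weigert_spec.__dict__, "seed": 8})
        rgb2, _ = generate_weigert_slide(other)
        assert not np.array_equal(rgb, rgb2)

    def test_zero_fraction_zone_has_no_fibers(self):
        spec = SlideSpec(width_px=256, height_px=256, seed=1,
                         fiber_fractions={"zone1": {"elastin": 0.0, "collagen": 0.0}})
        _, truth = generate_weigert_slide(spec)
        assert truth.per_zone_fiber_area["zone1"] == (0, 0)

    def test_rendered_fraction_matches_request(self, weigert_spec, weigert_slide):
        """Planted fiber pixel counts hit the requested fractions exactly."""
        _, truth = weigert_slide
        for zone, fracs in weigert_spec.fiber_fractions.items():
            n_zone = int((truth.zone_labels == CLASS_INDEX[zone]).sum())
            e_px, c_px = truth.per_zone_fiber_area[zone]
            assert e_px / n_zone == pytest.approx(fracs["elastin"], abs=0.01)
            assert c_px / n_zone == pytest.approx(fracs["collagen"], abs=0.01)

    def test_zone_textures_are_distinguishable(self, weigert_slide):
        rgb, truth = weigert_slide
        means = {}
        for zone in ("zone1", "zone2", "thrombus", "background"):
            mask = truth.zone_labels == CLASS_INDEX[zone]
            means[zone] = rgb[mask].mean(axis=0)
        zones = list(means)
        for i, a in enumerate(zones):
            for b in zones[i + 1 :]:
                assert np.linalg.norm(means[a] - means[b]) > 10.0

    def test_annotation_roundtrip_via_indexed_png(self, tmp_path, weigert_slide):
        from aaaquant.tiling import AnnotationMap

        _, truth = weigert_slide
        path = tmp_path / "ann.png"
        truth.annotation.save(path)
        loaded = AnnotationMap.load(path)
        assert np.array_equal(loaded.labels, truth.annotation.labels)


class TestIHCSlide:
    def test_zero_cells_gives_empty_truth(self):
        spec = SlideSpec(width_px=256, height_px=256, seed=2)
        _, truth = generate_ihc_slide(spec, {"zone1": 0}, {"zone1": 0.0})
        assert truth.planted_cells == []
        assert truth.per_zone_counts == {"zone1": (0, 0)}

    def test_positive_count_is_exact_by_construction(self, ihc_slide):
        _, truth = ihc_slide
        assert truth.per_zone_counts["zone1"] == (40, 20)
        assert truth.per_zone_counts["zone2"] == (25, 5)

    def test_counts_match_planted_cell_tally(self, ihc_slide):
        _, truth = ihc_slide
        for zone, (n, n_pos) in truth.per_zone_counts.items():
            cells = [c for c in truth.planted_cells if c.zone == zone]
            assert len(cells) == n
            assert sum(c.positive for c in cells) == n_pos

    def test_every_centroid_lies_inside_its_zone(self, ihc_slide):
        _, truth = ihc_slide
        for cell in truth.planted_cells:
            x, y = cell.centroid
            assert truth.zone_labels[int(round(y)), int(round(x))] == CLASS_INDEX[cell.zone]

    def test_infeasible_density_raises(self):
        spec = SlideSpec(width_px=128, height_px=128, seed=3)
        with pytest.raises(ValueError, match="density"):
            generate_ihc_slide(spec, {"zone1": 500}, {"zone1": 0.5})

    def test_different_seeds_move_cells(self, weigert_spec):
        a = generate_ihc_slide(weigert_spec, {"zone1": 10}, {"zone1": 0.5})[1]
        other = SlideSpec(**{**weigert_spec.__dict__, "seed": 99})
        b = generate_ihc_slide(other, {"zone1": 10}, {"zone1": 0.5})[1]
        assert {c.centroid for c in a.planted_cells} != {c.centroid for c in b.planted_cells}

    def test_forward_od_model_puts_dab_on_positive_compartment(self):
        """Unmixing the rendered image recovers DAB at the planted cells."""
        spec = SlideSpec(width_px=256, height_px=256, seed=4, noise_sigma=0.0)
        rgb, truth = generate_ihc_slide(spec, {"zone1": 8}, {"zone1": 1.0},
                                        dab_od=0.6)
        model = hdab_model()
        conc = unmix(od_transform(rgb, model.i0), model)
        dab = conc[..., 1]
        for cell in truth.planted_cells:
            x, y = (int(round(v)) for v in cell.centroid)
            assert dab[y, x] >= 0.5  # rendered 0.6 minus quantization
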