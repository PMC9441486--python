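import numpy as np
import pytest

from aaaquant.stains import hdab_model, mix
from aaaquant.synthetic import SlideSpec, generate_ihc_slide
from aaaquant.quantify import (
    CD8_PARAMS,
    MPO_PARAMS,
    DetectionParams,
    ZoneQuantRow,
    classify_fibers,
    detect_cells,
    stained_area,
    zone_report,
    zone_report_frame,
)


class TestDetectionParams:
    def test_published_qupath_settings(self):
        assert MPO_PARAMS.background_radius_um == 8.0
        assert MPO_PARAMS.threshold_compartment == "cytoplasm"
        assert MPO_PARAMS.positive_threshold == 0.2
        assert CD8_PARAMS.background_radius_um == 10.0
        assert CD8_PARAMS.threshold_compartment == "cell"
        assert CD8_PARAMS.positive_threshold == 0.1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(positive_threshold=0.0)
        with pytest.raises(ValueError):
            DetectionParams(min_nucleus_area_um2=500, max_nucleus_area_um2=100)


class TestDetectCells:
    def test_blank_image_yields_nothing(self):
        blank = np.full((128, 128, 3), 255, dtype=np.uint8)
        assert detect_cells(blank, CD8_PARAMS) == []

    def test_zero_noise_detection_is_exact_inverse(self):
        """100 planted cells, half DAB-positive, recovered exactly."""
        spec = SlideSpec(width_px=768, height_px=768, seed=3, noise_sigma=0.0)
        rgb, truth = generate_ihc_slide(spec, {"zone1": 100}, {"zone1": 0.5})
        detections = detect_cells(rgb, CD8_PARAMS, microns_per_px=spec.microns_per_px)
        assert len(detections) == 100
        assert sum(d.positive for d in detections) == 50

    def test_mpo_thresholds_cytoplasm_compartment(self):
        """Cytoplasm-only DAB is positive under MPO but has low nuclear OD."""
        spec = SlideSpec(width_px=512, height_px=512, seed=6, noise_sigma=0.0)
        rgb, truth = generate_ihc_slide(spec, {"zone1": 20}, {"zone1": 1.0},
                                        dab_compartment="cytoplasm", dab_od=0.5)
        detections = detect_cells(rgb, MPO_PARAMS, microns_per_px=spec.microns_per_px)
        assert len(detections) == 20
        assert all(d.positive for d in detections)
        # chromogen sits in the ring, so on average the cytoplasm carries
        # more DAB than the nucleus (segmentation borders blur single cells)
        assert np.mean([d.od_cytoplasm for d in detections]) > np.mean(
            [d.od_nucleus for d in detections]
        )

    def test_positive_flag_follows_compartment_od(self):
        spec = SlideSpec(width_px=512, height_px=512, seed=9, noise_sigma=0.0)
        rgb, _ = generate_ihc_slide(spec, {"zone1": 20}, {"zone1": 0.5})
        detections = detect_cells(rgb, CD8_PARAMS, microns_per_px=spec.microns_per_px)
        for d in detections:
            assert d.positive == (d.od_cell >= CD8_PARAMS.positive_threshold)


class TestStainedArea:
    def _dab_patch_image(self, mpp, side_px):
        img = np.zeros((512, 512, 3))
        conc = np.zeros((512, 512, 3))
        x0 = 256 - side_px // 2
        conc[x0 : x0 + side_px, x0 : x0 + side_px, 1] = 0.8
        return np.clip(mix(conc, hdab_model()), 0, 255).astype(np.uint8)

    def test_zero_dab_image_has_zero_area(self):
        blank = np.full((64, 64, 3), 255, dtype=np.uint8)
        frame = stained_area(blank, od_threshold=0.2)
        assert frame.stained_mm2.sum() == 0.0

    def test_planted_patch_area_recovered(self):
        mpp = 2.0  # 2 um/px so a 500-px square is 1 mm on a side
        side = 500
        img = self._dab_patch_image(mpp, side)
        frame = stained_area(img, od_threshold=0.2, microns_per_px=mpp)
        assert frame.stained_mm2.iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_monotone_in_threshold(self):
        img = self._dab_patch_image(2.0, 300)
        areas = [
            stained_area(img, od_threshold=t, microns_per_px=2.0).stained_mm2.iloc[0]
            for t in (0.05, 0.2, 0.5, 0.9, 2.0)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_threshold_above_max_od_gives_zero(self):
        img = self._dab_patch_image(2.0, 300)
        frame = stained_area(img, od_threshold=50.0, microns_per_px=2.0)
        assert frame.stained_mm2.iloc[0] == 0.0

    def test_per_zone_split(self, ihc_slide, truth_masks):
        rgb, _ = ihc_slide
        frame = stained_area(rgb, od_threshold=0.2, zone_masks=truth_masks)
        assert set(frame.zone) == {"zone1", "zone2", "thrombus", "background"}
        z1 = frame.set_index("zone").loc["zone1"]
        assert z1.stained_mm2 > 0  # DAB-positive cells were planted in zone 1


class TestClassifyFibers:
    def test_requested_collagen_fraction_recovered(self, weigert_slide, truth_masks):
        rgb, truth = weigert_slide
        frame = classify_fibers(rgb, zone_masks=truth_masks).set_index("zone")
        assert frame.loc["zone1", "collagen_pct"] == pytest.approx(30.0, abs=1.0)
        assert frame.loc["zone1", "elastin_pct"] == pytest.approx(25.0, abs=1.0)
        assert frame.loc["zone2", "collagen_pct"] == pytest.approx(40.0, abs=1.0)
        assert frame.loc["zone2", "elastin_pct"] == pytest.approx(5.0, abs=1.0)

    def test_dim_pixels_are_neither(self):
        # a pale image entirely below the minimum OD yields no fibers
        pale = np.full((64, 64, 3), 250, dtype=np.uint8)
        frame = classify_fibers(pale, min_total_od=0.15)
        assert frame.elastin_pct.iloc[0] == 0.0
        assert frame.collagen_pct.iloc[0] == 0.0

    def test_assignments_are_disjoint_and_bounded(self, weigert_slide, truth_masks):
        rgb, _ = weigert_slide
        frame = classify_fibers(rgb, zone_masks=truth_masks)
        for _, row in frame.iterrows():
            assert 0.0 <= row.elastin_pct <= 100.0
            assert 0.0 <= row.collagen_pct <= 100.0
            assert row.elastin_pct + row.collagen_pct <= 100.0


class TestZoneReport:
    def test_published_worked_ratios(self):
        """Detections/positives/area reproduce the reported derived columns."""
        row = ZoneQuantRow.build("zone1", 129_824, 12_308, 22.6)
        assert round(row.positive_pct, 1) == 9.5
        assert round(row.positives_per_mm2) == 545
        row2 = ZoneQuantRow.build("zone2", 48_472, 1_680, 22.0)
        assert round(row2.positive_pct, 1) == 3.5
        assert round(row2.positives_per_mm2) == 76

    def test_zero_detection_zone_guards_division(self):
        row = ZoneQuantRow.build("thrombus", 0, 0, 1.5)
        assert row.positive_pct == 0.0
        assert row.positives_per_mm2 == 0.0

    def test_positives_cannot_exceed_detections(self):
        with pytest.raises(ValueError):
            ZoneQuantRow.build("zone1", 5, 6, 1.0)

    def test_every_detection_assigned_exactly_once(self, ihc_slide, truth_masks):
        rgb, truth = ihc_slide
        detections = detect_cells(rgb, CD8_PARAMS,
                                  microns_per_px=truth.annotation.microns_per_px)
        rows = zone_report(detections, truth_masks)
        assert sum(r.detections for r in rows) == len(detections)

    def test_out_of_mask_detection_lands_in_background(self, truth_masks):
        from aaaquant.quantify import CellDetection

        det = CellDetection((1.0, 1.0), (0.45, 0.45), 50.0, 0.0, 0.0, 0.0, False)
        rows = {r.zone: r for r in zone_report([det], truth_masks)}
        assert rows["background"].detections == 1

    def test_report_frame_has_table_columns(self, truth_masks):
        frame = zone_report_frame(zone_report([], truth_masks))
        assert list(frame.columns) == [
            "Class", "Detections", "Positive", "Positive %",
            "Positive per mm^2", "Area [mm^2]",
        ]


class TestCountingRecovery:
    def test_recovery_within_five_percent_under_noise(self, ihc_slide, truth_masks):
        """Detections and positives per zone within +/-5% of planted truth."""
        rgb, truth = ihc_slide
        detections = detect_cells(rgb, CD8_PARAMS,
                                  microns_per_px=truth.annotation.microns_per_px)
        rows = {r.zone: r for r in zone_report(detections, truth_masks)}
        for zone, (n_true, n_pos_true) in truth.per_zone_counts.items():
            assert rows[zone].detections == pytest.approx(n_true, rel=0.05)
            assert rows[zone].positives == pytest.approx(n_pos_true, rel=0.05)
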