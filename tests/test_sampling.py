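import numpy as np
import pandas as pd
import pytest

from benthoscan import evaluate, sampling, synthetic
from benthoscan.sampling import (
    CameraGeometry,
    along_track_positions,
    check_overlap,
    decorrelation_check,
    footprint_area,
    partition_units,
    pool_and_standardise,
)
from benthoscan.geo import destination_east_m


def make_records(positions_m, dive_id="d1", altitude=3.0, lat=18.0, lon0=-23.0, depth=-3400.0):
    positions_m = np.asarray(positions_m, dtype=float)
    return pd.DataFrame(
        {
            "image_id": [f"{dive_id}_{i}" for i in range(len(positions_m))],
            "dive_id": dive_id,
            "timestamp_s": np.arange(len(positions_m), dtype=float),
            "lon_deg": destination_east_m(lon0, lat, positions_m),
            "lat_deg": lat,
            "depth_m": depth,
            "altitude_m": altitude,
        }
    )


class TestFootprint:
    def test_area_vanishes_with_altitude(self):
        assert footprint_area(1e-9) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle_geometry(self):
        geom = CameraGeometry(horizontal_angle=90.0, vertical_angle=90.0)
        assert footprint_area(1.0, geom) == pytest.approx(4.0)

    def test_survey_camera_at_three_metres(self):
        # 36 * tan(24 deg) * tan(16.5 deg)
        assert footprint_area(3.0) == pytest.approx(4.7475, abs=5e-4)

    def test_nonpositive_altitude_rejected(self):
        with pytest.raises(ValueError):
            footprint_area(0.0)


class TestAlongTrack:
    def test_single_image_at_origin(self):
        rec = along_track_positions(make_records([0.0]))
        assert rec["along_track_m"].iloc[0] == 0.0

    def test_equal_steps_accumulate(self):
        rec = along_track_positions(make_records([0, 10, 20, 30, 40]))
        assert np.allclose(rec["along_track_m"], [0, 10, 20, 30, 40], atol=1e-6)

    def test_duplicate_timestamps_rejected(self):
        records = make_records([0, 10])
        records.loc[1, "timestamp_s"] = 0.0
        with pytest.raises(ValueError):
            along_track_positions(records)


class TestOverlap:
    @pytest.mark.parametrize(
        "spacing, altitude, expect",
        [
            (10.0, 3.0, False),  # image length ~1.78 m << spacing
            (1.0, 3.0, True),  # spacing 1 m < image length
        ],
    )
    def test_overlap_flag(self, spacing, altitude, expect):
        rec = along_track_positions(make_records(np.arange(5) * spacing, altitude=altitude))
        out = check_overlap(rec)
        assert bool(out["overlap_flag"].iloc[0]) is expect

    def test_equality_counts_as_no_overlap(self):
        altitude = 3.0
        length = sampling.image_length_m(altitude)
        rec = along_track_positions(make_records(np.arange(4) * length, altitude=altitude))
        out = check_overlap(rec)
        assert out["mean_image_length_m"].iloc[0] == pytest.approx(out["mean_spacing_m"].iloc[0], rel=1e-6)
        assert not out["overlap_flag"].iloc[0]


class TestPartition:
    @pytest.mark.parametrize(
        "length, expected_edges",
        [
            (100.0, [(0.0, 100.0)]),
            (250.0, [(0.0, 100.0), (100.0, 200.0), (200.0, 250.0)]),
            (230.0, [(0.0, 100.0), (100.0, 230.0)]),
        ],
    )
    def test_remainder_rule(self, length, expected_edges):
        positions = np.arange(0, length + 1, 10.0)
        rec = make_records(positions)
        rec["along_track_m"] = positions  # exact positions, no geodesy round-trip
        units, _ = partition_units(rec)
        got = list(zip(units["start_m"], units["end_m"]))
        assert got == pytest.approx(expected_edges)

    def test_every_image_assigned_exactly_once(self):
        rec = along_track_positions(make_records(np.arange(0, 351, 7.0)))
        units, rec = partition_units(rec)
        assert rec["unit_id"].notna().all()
        assert units["n_images"].sum() == len(rec)


class TestPoolAndStandardise:
    @staticmethod
    def _detections(image_ids, taxon="Porifera"):
        n = len(image_ids)
        return pd.DataFrame(
            {"image_id": image_ids, "taxon": taxon, "x": 0, "y": 0, "w": 4, "h": 4,
             "confidence": 0.9}
        )

    def test_abundance_is_count_over_area(self):
        rec = along_track_positions(make_records(np.arange(0, 100, 10.0)))
        units, rec = partition_units(rec)
        det = self._detections(list(rec["image_id"]))  # 1 per image
        m = pool_and_standardise(units, rec, det)
        area = footprint_area(3.0) * len(rec)
        assert m.abundance.iloc[0, 0] == pytest.approx(len(rec) / area)

    def test_zero_detections_zero_row(self):
        rec = along_track_positions(make_records(np.arange(0, 100, 10.0)))
        units, rec = partition_units(rec)
        det = self._detections([])
        m = pool_and_standardise(units, rec, det, taxa=["Porifera"])
        assert (m.abundance.to_numpy() == 0).all()

    def test_duplicating_images_and_detections_preserves_abundances(self, default_survey):
        _, records, detections, truth = default_survey
        units, rec = partition_units(records)
        m1 = pool_and_standardise(units, rec, detections, region_map=truth.region_of_dive)
        dup_rec = pd.concat([rec, rec.assign(image_id=rec["image_id"] + "_dup")], ignore_index=True)
        dup_det = pd.concat(
            [detections, detections.assign(image_id=detections["image_id"] + "_dup")],
            ignore_index=True)
        units2 = units.copy()
        units2["n_images"] *= 2
        m2 = pool_and_standardise(units2, dup_rec, dup_det, region_map=truth.region_of_dive)
        pd.testing.assert_frame_equal(m1.abundance, m2.abundance, check_exact=False, atol=1e-12)
        assert (m2.counts.to_numpy() == 2 * m1.counts.to_numpy()).all()

    def test_counts_are_conserved(self, abundance_matrix, default_survey):
        matrix, _ = abundance_matrix
        _, _, detections, _ = default_survey
        per_taxon = detections.groupby("taxon").size()
        for taxon, total in per_taxon.items():
            assert matrix.counts[taxon].sum() == total

    def test_unknown_detection_image_rejected(self):
        rec = along_track_positions(make_records(np.arange(0, 100, 10.0)))
        units, rec = partition_units(rec)
        det = self._detections(["ghost"])
        with pytest.raises(ValueError):
            pool_and_standardise(units, rec, det)


class TestDecorrelation:
    def test_exact_proportionality_gives_r_one_and_undefined(self, rng):
        # square 90x90-degree camera: area = 4 h^2, so integer areas are exact
        geom = CameraGeometry(horizontal_angle=90.0, vertical_angle=90.0)
        rec = along_track_positions(make_records(np.arange(0, 500, 10.0)))
        areas = rng.integers(4, 20, size=len(rec))
        rec["altitude_m"] = np.sqrt(areas / 4.0)
        units, rec = partition_units(rec)
        # counts exactly 2 per m^2: abundance is exactly constant
        det = self._make_det(np.repeat(rec["image_id"].to_numpy(), 2 * areas))
        m = pool_and_standardise(units, rec, det, geometry=geom)
        out = decorrelation_check(m)
        assert out["r_counts_area"].iloc[0] > 0.99
        assert np.isnan(out["r_abundance_area"].iloc[0])

    @staticmethod
    def _make_det(image_ids):
        return pd.DataFrame(
            {"image_id": image_ids, "taxon": "Porifera", "x": 0, "y": 0, "w": 4, "h": 4,
             "confidence": 1.0}
        )

    def test_constant_intensity_survey_decorrelates(self):
        summary = evaluate.decorrelation_summary(range(5))
        assert summary["r_counts_area"].mean() > 0.5
        assert abs(summary["r_abundance_area"]).mean() < 0.2


class TestRegionalRecovery:
    def test_regional_means_within_fifteen_percent(self):
        df = evaluate.regional_recovery(range(10))
        est_ratio = df["est_ratio"].mean()
        true_ratio = df["true_ratio"].iloc[0]
        assert est_ratio == pytest.approx(true_ratio, rel=0.15)
        assert df["est_east"].mean() == pytest.approx(df["true_east"].iloc[0], rel=0.15)
        assert df["est_west"].mean() == pytest.approx(df["true_west"].iloc[0], rel=0.15)
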