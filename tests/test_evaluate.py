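"""QWA evaluation metrics: pixel agreement, spacing, vessel mismatch,
expert-agreement summaries."""

import itertools
import math

import numpy as np
import pytest

from ringseg.evaluate import (
    BoundaryMatch,
    EvalRecord,
    assign_vessels,
    boundary_mean_position,
    center_distance,
    match_boundaries,
    pixel_agreement,
    px_to_um,
    summarize_agreement,
    summary_from_counts,
    truncate_decimals,
    vessel_mismatch,
)
from ringseg.synthetic import rasterize_boundaries
from ringseg.types import BoundaryPath, VesselRecord


def _line(row, cols=np.arange(100.0), source="manual"):
    rows = np.full_like(np.asarray(cols, float), row)
    return BoundaryPath(np.column_stack([rows, cols]), source)


class TestPixelAgreement:
    def test_identical_masks_perfect(self):
        m = np.zeros((10, 10), np.uint8)
        m[4] = 1
        assert pixel_agreement(m, m) == (1.0, 1.0, 1.0, 1.0)

    def test_one_pixel_offset_lines_score_zero(self):
        """Two complete, equally segmented lines one pixel apart share no
        foreground, so pixel-level matching collapses to zero."""
        a = np.zeros((10, 10), np.uint8)
        b = np.zeros((10, 10), np.uint8)
        a[4] = 1
        b[5] = 1
        precision, recall, f1, iou = pixel_agreement(a, b)
        assert f1 == 0.0 and iou == 0.0

    def test_empty_vs_empty_defined_as_one(self):
        z = np.zeros((5, 5), np.uint8)
        assert pixel_agreement(z, z) == (1.0, 1.0, 1.0, 1.0)

    def test_matches_brute_force_confusion(self, rng):
        for _ in range(20):
            a = (rng.uniform(size=(8, 8)) < 0.4).astype(np.uint8)
            b = (rng.uniform(size=(8, 8)) < 0.4).astype(np.uint8)
            tp = fp = fn = 0
            for i in range(8):
                for j in range(8):
                    tp += a[i, j] and b[i, j]
                    fp += (not a[i, j]) and b[i, j]
                    fn += a[i, j] and not b[i, j]
            precision, recall, f1, iou = pixel_agreement(a, b)
            if tp + fp:
                assert precision == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert recall == pytest.approx(tp / (tp + fn))
            if tp + fp + fn:
                assert iou == pytest.approx(tp / (tp + fp + fn))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            pixel_agreement(np.zeros((4, 4)), np.zeros((4, 5)))


class TestMeanPosition:
    def test_single_point(self):
        assert boundary_mean_position(
            BoundaryPath(np.array([[5.0, 7.0]]))
        ) == (5.0, 7.0)

    def test_horizontal_line(self):
        assert boundary_mean_position(_line(10.0)) == (10.0, 49.5)

    def test_v_shape_matches_hand_sum(self):
        pts = np.array([[4.0, 0.0], [2.0, 1.0], [0.0, 2.0], [2.0, 3.0], [4.0, 4.0]])
        assert boundary_mean_position(BoundaryPath(pts)) == (
            pts[:, 0].sum() / 5,
            pts[:, 1].sum() / 5,
        )


class TestCenterDistance:
    def test_identical_is_zero(self):
        assert center_distance(_line(10), _line(10, source="model")) == 0.0

    def test_row_offset(self):
        assert center_distance(_line(10), _line(20, source="model")) == 10.0

    def test_row_mode_projects_growth_axis(self):
        a = _line(10, cols=np.arange(50.0))
        b = _line(14, cols=np.arange(30.0, 80.0), source="model")
        assert center_distance(a, b, mode="row") == 4.0
        assert center_distance(a, b) == pytest.approx(math.hypot(4.0, 30.0))

    def test_reported_pixel_to_micron_conversion(self):
        """35.85 px at 1.63 um/px is 58.43 um after two-decimal truncation."""
        assert truncate_decimals(px_to_um(35.85, 1.63)) == 58.43


class TestMatchBoundaries:
    def test_identical_lists_all_matched(self):
        manual = [_line(r) for r in (10, 40, 70)]
        pred = [_line(r, source="model") for r in (10, 40, 70)]
        matches = match_boundaries(manual, pred, gate_px=15)
        assert all(m.matched and m.center_distance_px == 0 for m in matches)

    def test_extra_prediction_far_away_is_predicted_only(self):
        matches = match_boundaries(
            [_line(10)], [_line(10, source="model"), _line(90, source="model")],
            gate_px=15,
        )
        assert sum(m.predicted_only for m in matches) == 1
        assert sum(m.matched for m in matches) == 1

    def test_missed_manual_is_manual_only(self):
        matches = match_boundaries([_line(10), _line(80)], [_line(11, source="model")],
                                   gate_px=15)
        assert sum(m.manual_only for m in matches) == 1

    def test_assignment_matches_exhaustive_permutation_search(self, rng):
        for trial in range(5):
            m_rows = rng.uniform(0, 100, size=4)
            p_rows = m_rows + rng.normal(0, 8, size=4)
            manual = [_line(r) for r in m_rows]
            pred = [_line(r, source="model") for r in p_rows]
            gate = 25.0
            matches = match_boundaries(manual, pred, gate_px=gate)
            got = sum(m.center_distance_px for m in matches if m.matched)

            best = math.inf
            for perm in itertools.permutations(range(4)):
                total, n = 0.0, 0
                for i, j in enumerate(perm):
                    d = abs(m_rows[i] - p_rows[j])
                    if d <= gate:
                        total += d
                        n += 1
                if n == sum(m.matched for m in matches):
                    best = min(best, total)
            assert got == pytest.approx(best)

    def test_empty_inputs(self):
        assert match_boundaries([], [], 10) == []
        matches = match_boundaries([], [_line(5, source="model")], 10)
        assert len(matches) == 1 and matches[0].predicted_only


class TestAssignVessels:
    def test_vessel_above_first_boundary_is_ring_zero(self):
        idx = assign_vessels([_line(50)], [VesselRecord((10.0, 5.0))])
        assert idx.tolist() == [0]

    def test_no_boundaries_all_ring_zero(self):
        idx = assign_vessels([], [VesselRecord((10.0, 5.0)), VesselRecord((90.0, 5.0))])
        assert idx.tolist() == [0, 0]

    def test_horizontal_extension_beyond_span(self):
        short = BoundaryPath(np.array([[20.0, 40.0], [24.0, 60.0]]))
        # at col 0 the boundary extends horizontally from row 20
        assert assign_vessels([short], [VesselRecord((25.0, 0.0))]).tolist() == [1]
        assert assign_vessels([short], [VesselRecord((15.0, 0.0))]).tolist() == [0]

    def test_matches_rasterized_band_oracle(self, rng):
        """Ring index equals a brute-force label built by flood-counting
        rasterized boundary rows downward through each column."""
        h, w = 120, 80
        cols = np.arange(float(w))
        boundaries = []
        for base in (30.0, 70.0):
            rows = base + 5 * np.sin(cols / 13.0 + base)
            boundaries.append(BoundaryPath(np.column_stack([rows, cols])))
        dense = np.stack([b.row_at(cols) for b in boundaries])
        # integer columns so interpolation coincides with the dense raster
        vessels = [
            VesselRecord((float(rng.uniform(0, h - 1)), float(rng.integers(0, w))))
            for _ in range(200)
        ]
        got = assign_vessels(boundaries, vessels, image_width=w)
        for v, g in zip(vessels, got):
            r, c = v.center
            expected = int((dense[:, int(c)] < r).sum())
            assert g == expected

    def test_vessel_conservation(self, small_sample):
        idx = assign_vessels(small_sample.boundaries, small_sample.vessels)
        counts = np.bincount(idx, minlength=len(small_sample.boundaries) + 1)
        assert counts.sum() == len(small_sample.vessels)
        assert idx.min() >= 0 and idx.max() <= len(small_sample.boundaries)

    def test_crossing_boundaries_rejected(self):
        a = BoundaryPath(np.array([[10.0, 0.0], [40.0, 99.0]]))
        b = BoundaryPath(np.array([[40.0, 0.0], [10.0, 99.0]]))
        with pytest.raises(ValueError, match="cross"):
            assign_vessels([a, b], [VesselRecord((5.0, 5.0))], image_width=100)


class TestVesselMismatch:
    def test_identical_boundaries_zero(self):
        pair = BoundaryMatch(_line(30), _line(30, source="model"), 0.0)
        vessels = [VesselRecord((r, 50.0)) for r in (10.0, 29.0, 31.0, 90.0)]
        assert vessel_mismatch(pair, vessels) == 0

    def test_single_vessel_in_shifted_gap(self):
        pair = BoundaryMatch(_line(30), _line(35, source="model"), 5.0)
        vessels = [VesselRecord((32.0, 50.0)), VesselRecord((10.0, 50.0)),
                   VesselRecord((80.0, 50.0))]
        assert vessel_mismatch(pair, vessels) == 1

    def test_symmetric_in_delineations(self, rng):
        a = _line(30)
        b = _line(38, source="model")
        vessels = [
            VesselRecord((float(rng.uniform(0, 100)), float(rng.uniform(0, 99))))
            for _ in range(50)
        ]
        assert vessel_mismatch(BoundaryMatch(a, b, 0.0), vessels) == vessel_mismatch(
            BoundaryMatch(b, a, 0.0), vessels
        )

    def test_matches_per_vessel_side_oracle(self, rng):
        cols = np.arange(100.0)
        a = BoundaryPath(np.column_stack([40 + 4 * np.sin(cols / 9), cols]))
        b = BoundaryPath(
            np.column_stack([44 + 4 * np.cos(cols / 7), cols]), source="model"
        )
        vessels = [
            VesselRecord((float(rng.uniform(20, 70)), float(rng.uniform(0, 99))))
            for _ in range(100)
        ]
        expected = 0
        for v in vessels:
            r, c = v.center
            expected += (float(a.row_at(c)) < r) != (float(b.row_at(c)) < r)
        assert vessel_mismatch(BoundaryMatch(a, b, 0.0), vessels) == expected

    def test_unmatched_pair_rejected(self):
        with pytest.raises(ValueError):
            vessel_mismatch(BoundaryMatch(manual=_line(10)), [])


class TestSummarizeAgreement:
    def test_reference_counts_reproduce_reported_percentages(self):
        """Counts 108/619/601 of 1329 rings give 8.12 / 46.57 / 45.22 %,
        91.79 % equal-or-better, and 8.1 % at one decimal."""
        s = summary_from_counts(108, 619, 601, 1329)
        assert s.percentages == {"manual": 8.12, "similar": 46.57, "model": 45.22}
        assert s.equal_or_better_pct == 91.79
        assert truncate_decimals(s.raw_percentages["manual"], 1) == 8.1

    def test_single_model_record(self):
        rec = EvalRecord(BoundaryMatch(_line(1), _line(2, source="model"), 1.0), 2)
        s = summarize_agreement([rec], total_rings=1)
        assert s.percentages == {"manual": 0.0, "similar": 0.0, "model": 100.0}

    def test_mean_and_se_definitions(self):
        recs = []
        for d, vm in [(10.0, 1), (20.0, 3)]:
            m = BoundaryMatch(_line(1), _line(2, source="model"), d)
            m.vessel_mismatch = vm
            recs.append(EvalRecord(m, 2))
        s = summarize_agreement(recs, total_rings=2)
        mean, se = s.center_distance_mean_se["model"]
        assert mean == 15.0
        assert se == pytest.approx(np.std([10, 20], ddof=1) / math.sqrt(2))
        vmean, _ = s.vessel_mismatch_mean_se["model"]
        assert vmean == 2.0

    def test_unlabeled_record_rejected(self):
        rec = EvalRecord(BoundaryMatch(_line(1), _line(2, source="model"), 1.0), None)
        with pytest.raises(ValueError):
            summarize_agreement([rec], 1)

    def test_counts_cannot_exceed_total(self):
        rec = EvalRecord(BoundaryMatch(_line(1), _line(2, source="model"), 1.0), 1)
        with pytest.raises(ValueError):
            summarize_agreement([rec, rec], 1)


def test_truncation_not_rounding():
    assert truncate_decimals(46.576, 2) == 46.57  # rounding would give 46.58
    assert truncate_decimals(91.798, 2) == 91.79


def test_known_shift_recovered_on_synthetic_sample(small_sample):
    """Shifting the true delineation by delta rows moves every mean-center
    distance by exactly delta."""
    delta = 7.0
    shifted = [
        BoundaryPath(b.points + np.array([delta, 0.0]), source="model")
        for b in small_sample.boundaries
    ]
    matches = match_boundaries(small_sample.boundaries, shifted, gate_px=50)
    dists = [m.center_distance_px for m in matches if m.matched]
    assert len(dists) == len(small_sample.boundaries)
    assert np.allclose(dists, delta, atol=0.5)
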