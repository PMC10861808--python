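import numpy as np
import pytest

from tests.conftest import random_mask
from tractconc.ntms import (
    CLASSES,
    EXCLUDED,
    NEG_OUT_M1,
    POS_IN_M1,
    POS_OUT_M1,
    ClassifiedResponseMask,
    ResponseRecord,
    build_response_masks,
    classify_response,
    rasterize_responses,
    remove_landmarks,
    threshold_export,
    wm_filter,
)
from tractconc.volumes import BinaryMask, Grid, GridMismatchError, Volume


@pytest.fixture
def m1_mask():
    data = np.zeros((10, 10, 10), dtype=np.uint8)
    data[4:7, 4:7, 4:7] = 1
    return BinaryMask(data, np.eye(4))


def rec(pos, amp, lat, **kw):
    return ResponseRecord(position=pos, amplitude=amp, latency=lat, **kw)


class TestClassify:
    def test_positive_inside_m1(self, m1_mask):
        assert classify_response(rec((5, 5, 5), 60, 20), m1_mask) == POS_IN_M1

    def test_amplitude_exactly_at_threshold_is_positive(self, m1_mask):
        assert classify_response(rec((1, 1, 1), 50, 22), m1_mask) == POS_OUT_M1

    def test_negative_inside_m1_excluded(self, m1_mask):
        assert classify_response(rec((5, 5, 5), 30, 21), m1_mask) == EXCLUDED

    def test_latency_out_of_window_excluded(self, m1_mask):
        assert classify_response(rec((1, 1, 1), 30, 30), m1_mask) == EXCLUDED

    def test_latency_bounds_inclusive(self, m1_mask):
        assert classify_response(rec((1, 1, 1), 60, 18), m1_mask) == POS_OUT_M1
        assert classify_response(rec((1, 1, 1), 60, 26), m1_mask) == POS_OUT_M1

    def test_negative_outside_m1(self, m1_mask):
        assert classify_response(rec((1, 1, 1), 30, 21), m1_mask) == NEG_OUT_M1

    def test_position_outside_extent_excluded_with_warning(self, m1_mask, caplog):
        with caplog.at_level("WARNING"):
            out = classify_response(rec((50, 50, 50), 60, 20), m1_mask)
        assert out == EXCLUDED
        assert "registration" in caplog.text

    def test_manual_exclusion_flag(self, m1_mask):
        r = rec((5, 5, 5), 60, 20, manually_excluded=True)
        assert classify_response(r, m1_mask) == EXCLUDED

    def test_totality(self, m1_mask, rng):
        # every record maps to exactly one of the four outcomes
        outcomes = {POS_IN_M1, POS_OUT_M1, NEG_OUT_M1, EXCLUDED}
        for _ in range(200):
            r = rec(
                tuple(rng.uniform(-2, 12, 3)),
                float(rng.uniform(0, 120)),
                float(rng.uniform(10, 35)),
            )
            assert classify_response(r, m1_mask) in outcomes

    def test_invalid_record_rejected(self):
        with pytest.raises(ValueError):
            ResponseRecord(position=(0, 0, 0), amplitude=-1, latency=20)
        with pytest.raises(ValueError):
            ResponseRecord(position=(0, 0, 0), amplitude=50, latency=float("nan"))


class TestThresholdExport:
    def test_all_zero(self):
        out = threshold_export(Volume(np.zeros((4, 4, 4)), np.eye(4)))
        assert out.foreground_count == 0

    def test_tiny_positive_is_foreground(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = 0.0001
        assert threshold_export(Volume(data, np.eye(4))).data[1, 1, 1] == 1

    def test_negative_is_background(self):
        data = np.zeros((4, 4, 4))
        data[1, 1, 1] = -3.0
        assert threshold_export(Volume(data, np.eye(4))).foreground_count == 0


class TestMaskFilters:
    def test_subset_unchanged(self, rng):
        inner = np.zeros((8, 8, 8), dtype=np.uint8)
        inner[3:5, 3:5, 3:5] = 1
        outer = np.ones((8, 8, 8), dtype=np.uint8)
        out = remove_landmarks(BinaryMask(inner, np.eye(4)), BinaryMask(outer, np.eye(4)))
        assert np.array_equal(out.data, inner)

    def test_disjoint_empty(self):
        a = np.zeros((8, 8, 8), dtype=np.uint8)
        a[0, 0, 0] = 1
        b = np.zeros((8, 8, 8), dtype=np.uint8)
        b[7, 7, 7] = 1
        out = remove_landmarks(BinaryMask(a, np.eye(4)), BinaryMask(b, np.eye(4)))
        assert out.foreground_count == 0

    @pytest.mark.parametrize("op", [remove_landmarks, wm_filter])
    def test_random_masks_match_voxel_loop_and(self, op, rng):
        a, b = random_mask(rng), random_mask(rng)
        out = op(a, b)
        for i in range(8):
            for j in range(8):
                for k in range(8):
                    assert out.data[i, j, k] == (a.data[i, j, k] and b.data[i, j, k])

    def test_grid_mismatch_mentions_resample(self):
        a = BinaryMask(np.zeros((4, 4, 4), dtype=np.uint8), np.eye(4))
        b = BinaryMask(np.zeros((5, 5, 5), dtype=np.uint8), np.eye(4))
        with pytest.raises(GridMismatchError, match="resample_to_grid"):
            remove_landmarks(a, b)

    def test_filters_never_increase_foreground(self, rng):
        for _ in range(20):
            a, b = random_mask(rng), random_mask(rng)
            assert remove_landmarks(a, b).foreground_count <= a.foreground_count
            assert wm_filter(a, b).foreground_count <= a.foreground_count

    def test_wm_filter_complement_flag(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        keep = wm_filter(a, b, keep_in_wm=True)
        drop = wm_filter(a, b, keep_in_wm=False)
        assert keep.foreground_count + drop.foreground_count == a.foreground_count


class TestRasterize:
    GRID = Grid((11, 11, 11), np.eye(4))

    def test_single_record_radius_zero(self):
        crm = rasterize_responses([rec((5, 5, 5), 60, 20)], self.GRID, POS_IN_M1)
        assert crm.mask.foreground_count == 1
        assert crm.mask.data[5, 5, 5] == 1
        assert crm.n_responses == 1

    def test_radius_gives_face_neighbour_cross(self):
        # voxel centers within 1.5 mm of (5,5,5) on a 1 mm grid: the center
        # plus its 6 face neighbours (diagonals are at sqrt(2) > 1.5? no —
        # sqrt(2) ~= 1.414 < 1.5, so the 12 edge neighbours count too).
        # enumerate explicitly:
        expected = set()
        for i in range(11):
            for j in range(11):
                for k in range(11):
                    if np.linalg.norm(np.array([i, j, k]) - 5.0) <= 1.5:
                        expected.add((i, j, k))
        crm = rasterize_responses([rec((5, 5, 5), 60, 20)], self.GRID, POS_IN_M1, radius=1.5)
        got = set(map(tuple, np.argwhere(crm.mask.data > 0)))
        assert got == expected

    def test_radius_one_is_cross(self):
        crm = rasterize_responses([rec((5, 5, 5), 60, 20)], self.GRID, POS_IN_M1, radius=1.0)
        assert crm.mask.foreground_count == 7  # center + 6 face neighbours

    def test_coincident_records_idempotent(self):
        crm = rasterize_responses(
            [rec((5, 5, 5), 60, 20), rec((5, 5, 5), 70, 21)], self.GRID, POS_IN_M1
        )
        assert crm.mask.foreground_count == 1
        assert crm.n_responses == 2

    def test_empty_records(self):
        crm = rasterize_responses([], self.GRID, NEG_OUT_M1)
        assert crm.mask.foreground_count == 0
        assert crm.n_responses == 0

    def test_bad_class_rejected(self):
        with pytest.raises(ValueError, match="klass"):
            ClassifiedResponseMask(
                BinaryMask(np.zeros((4, 4, 4), dtype=np.uint8), np.eye(4)), "bogus", 0
            )


class TestBuildResponseMasks:
    def test_classes_pairwise_disjoint(self, m1_mask, rng):
        full = BinaryMask(np.ones((10, 10, 10), dtype=np.uint8), np.eye(4))
        records = [
            rec(tuple(rng.uniform(0, 9.4, 3)), float(rng.uniform(0, 120)), 20.0)
            for _ in range(60)
        ]
        masks = build_response_masks(records, m1_mask, full, full)
        assert set(masks) == set(CLASSES)
        combined = sum(masks[k].mask.data.astype(int) for k in CLASSES)
        assert combined.max() <= 1

    def test_landmarks_removed(self, m1_mask):
        intracranial = np.zeros((10, 10, 10), dtype=np.uint8)
        intracranial[2:8, 2:8, 2:8] = 1
        full = BinaryMask(np.ones((10, 10, 10), dtype=np.uint8), np.eye(4))
        records = [rec((5, 5, 5), 60, 20), rec((9, 9, 9), 60, 20)]  # second is a landmark
        masks = build_response_masks(
            records, m1_mask, BinaryMask(intracranial, np.eye(4)), full
        )
        assert masks[POS_IN_M1].mask.foreground_count == 1
        assert masks[POS_OUT_M1].mask.foreground_count == 0
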