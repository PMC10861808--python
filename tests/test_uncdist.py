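import numpy as np
import pytest

from tests.conftest import random_mask, random_volume
from tractconc.ntms import POS_IN_M1, ClassifiedResponseMask
from tractconc.uncdist import (
    binned_spearman,
    distance_map,
    joint_histogram,
    linear_trend,
    pair_uncertainty_distance,
    spearman,
)
from tractconc.volumes import BinaryMask, Volume


def brute_force_distance(mask: BinaryMask) -> np.ndarray:
    """O(n^2) oracle: per-voxel minimum distance over all foreground centers."""
    fg = np.argwhere(mask.data > 0).astype(float) * mask.spacing
    out = np.zeros(mask.shape)
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            for k in range(mask.shape[2]):
                p = np.array([i, j, k]) * mask.spacing
                out[i, j, k] = np.min(np.linalg.norm(fg - p, axis=1))
    return out


class TestDistanceMap:
    def test_zero_on_foreground(self, rng):
        m = random_mask(rng, p=0.3)
        d = distance_map(m)
        assert np.all(d.data[m.data > 0] == 0)

    def test_face_neighbour_isotropic(self):
        data = np.zeros((5, 5, 5), dtype=np.uint8)
        data[2, 2, 2] = 1
        d = distance_map(BinaryMask(data, np.eye(4)))
        assert d.data[2, 2, 3] == pytest.approx(1.0)

    def test_anisotropic_spacing(self):
        data = np.zeros((5, 5, 5), dtype=np.uint8)
        data[2, 2, 2] = 1
        d = distance_map(BinaryMask(data, np.diag([1.0, 1.0, 2.0, 1.0])))
        assert d.data[2, 2, 3] == pytest.approx(2.0)
        assert d.data[2, 3, 2] == pytest.approx(1.0)

    def test_empty_mask_error(self):
        with pytest.raises(ValueError, match="empty"):
            distance_map(BinaryMask(np.zeros((4, 4, 4), dtype=np.uint8), np.eye(4)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        affine = np.diag([1.0, 1.0, rng.choice([1.0, 2.0]), 1.0])
        m = random_mask(rng, shape=(8, 8, 8), p=0.1, affine=affine)
        if m.foreground_count == 0:
            m.data[0, 0, 0] = 1
        d = distance_map(m)
        assert np.allclose(d.data, brute_force_distance(m), atol=1e-9)

    def test_lipschitz_across_neighbours(self, rng):
        m = random_mask(rng, shape=(8, 8, 8), p=0.1)
        m.data[4, 4, 4] = 1
        d = distance_map(m).data
        for axis in range(3):
            step = np.abs(np.diff(d, axis=axis))
            assert step.max() <= m.spacing[axis] + 1e-9


class TestPairing:
    def test_empty_response_mask(self, rng):
        m = random_mask(rng, p=0.3)
        d = distance_map(m)
        unc = random_volume(rng)
        empty = ClassifiedResponseMask(
            BinaryMask(np.zeros((8, 8, 8), dtype=np.uint8), np.eye(4)), POS_IN_M1, 0
        )
        assert len(pair_uncertainty_distance(unc, d, empty)) == 0

    def test_in_tract_voxel_has_zero_distance(self, rng):
        m = random_mask(rng, p=0.3)
        m.data[3, 3, 3] = 1
        d = distance_map(m)
        unc = random_volume(rng)
        resp = np.zeros((8, 8, 8), dtype=np.uint8)
        resp[3, 3, 3] = 1
        pairs = pair_uncertainty_distance(unc, d, BinaryMask(resp, np.eye(4)))
        assert pairs.shape == (1, 2)
        assert pairs[0, 1] == 0.0

    def test_matches_voxel_loop(self, rng):
        m = random_mask(rng, p=0.2)
        m.data[0, 0, 0] = 1
        d = distance_map(m)
        unc = random_volume(rng)
        resp = random_mask(rng, p=0.2)
        pairs = pair_uncertainty_distance(unc, d, resp)
        expected = [
            (unc.data[i, j, k], d.data[i, j, k])
            for i in range(8)
            for j in range(8)
            for k in range(8)
            if resp.data[i, j, k]
        ]
        assert np.allclose(pairs, expected)


class TestJointHistogram:
    def test_single_bin_pools_everything(self):
        pairs = np.array([[1.0, 0.2], [2.0, 0.4], [3.0, 0.1]])
        h = joint_histogram(pairs, n_bins=1)
        assert h.counts.tolist() == [3]
        assert h.means[0] == pytest.approx(2.0)
        assert h.stds[0] == pytest.approx(np.std([1, 2, 3]))

    def test_manual_two_bin_case(self):
        # distances 1,2 fall in [0,5); 6,9 fall in [5,10] (upper bin closed)
        pairs = np.array([[1.0, 1.0], [3.0, 2.0], [5.0, 6.0], [7.0, 9.0]])
        h = joint_histogram(pairs, n_bins=2)
        assert np.allclose(h.bin_edges, [0.0, 4.5, 9.0])
        assert h.counts.tolist() == [2, 2]
        assert h.means[0] == pytest.approx(2.0)
        assert h.means[1] == pytest.approx(6.0)
        assert h.stds[0] == pytest.approx(1.0)
        assert h.stds[1] == pytest.approx(1.0)

    def test_counts_conserve_input_size(self, rng):
        pairs = np.column_stack([rng.random(500), rng.random(500) * 20])
        h = joint_histogram(pairs, n_bins=30)
        assert h.counts.sum() == 500
        assert len(h.bin_edges) == 31
        assert np.all(np.diff(h.bin_edges) > 0)

    def test_max_distance_lands_in_last_bin(self, rng):
        pairs = np.array([[0.5, 0.0], [0.5, 10.0]])
        h = joint_histogram(pairs, n_bins=5)
        assert h.counts[-1] == 1

    def test_empty_bins_flagged_nan(self):
        pairs = np.array([[1.0, 0.0], [2.0, 10.0]])
        h = joint_histogram(pairs, n_bins=5)
        assert np.isnan(h.means[2])
        assert h.counts[2] == 0

    def test_all_distances_identical_degenerate(self, caplog):
        pairs = np.array([[1.0, 0.0], [2.0, 0.0]])
        with caplog.at_level("WARNING"):
            h = joint_histogram(pairs, n_bins=30)
        assert h.n_bins == 1
        assert h.counts[0] == 2
        assert "degenerate" in caplog.text

    def test_singleton_bin_std_zero(self):
        pairs = np.array([[1.0, 0.0], [2.0, 9.9]])
        h = joint_histogram(pairs, n_bins=2)
        assert h.stds[0] == 0.0

    def test_permutation_invariance(self, rng):
        pairs = np.column_stack([rng.random(100), rng.random(100) * 5])
        h1 = joint_histogram(pairs, 10)
        h2 = joint_histogram(pairs[rng.permutation(100)], 10)
        assert np.allclose(h1.means, h2.means, equal_nan=True)
        assert np.array_equal(h1.counts, h2.counts)


class TestSpearman:
    def test_perfect_negative(self):
        d = np.arange(10.0)
        u = 5.0 - 0.3 * d
        rho, p = spearman(np.column_stack([u, d]))
        assert rho == pytest.approx(-1.0)
        assert p < 0.01

    def test_perfect_positive(self):
        d = np.arange(10.0)
        rho, _ = spearman(np.column_stack([d, d]))
        assert rho == pytest.approx(1.0)

    def test_monotone_nonlinear_still_perfect(self):
        d = np.arange(1.0, 9.0)
        u = np.exp(-d)  # monotone but nonlinear
        rho, _ = spearman(np.column_stack([u, d]))
        assert rho == pytest.approx(-1.0)

    def test_tied_ranks_manual_case(self):
        # d=(1,2,2,3), u=(2,1,4,3): average ranks
        # rank(d) = (1, 2.5, 2.5, 4); rank(u) = (2, 1, 4, 3)
        d = np.array([1.0, 2.0, 2.0, 3.0])
        u = np.array([2.0, 1.0, 4.0, 3.0])
        rd = np.array([1.0, 2.5, 2.5, 4.0])
        ru = np.array([2.0, 1.0, 4.0, 3.0])
        expected = np.corrcoef(ru, rd)[0, 1]
        rho, _ = spearman(np.column_stack([u, d]))
        assert rho == pytest.approx(expected)

    def test_exact_permutation_small_n(self):
        # n=4: exact permutation p over 24 orderings
        d = np.array([1.0, 2.0, 3.0, 4.0])
        u = np.array([4.0, 3.0, 2.0, 1.0])
        rho, p = spearman(np.column_stack([u, d]))
        assert rho == pytest.approx(-1.0)
        # only 2 of 24 permutations achieve |rho| = 1
        assert p == pytest.approx(2 / 24)

    def test_zero_variance_undefined(self):
        pairs = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="variance"):
            spearman(pairs)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="at least 3"):
            spearman(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestLinearTrend:
    def test_exact_fit(self):
        d = np.linspace(0, 10, 20)
        u = 3.0 - 0.5 * d
        slope, intercept = linear_trend(np.column_stack([u, d]))
        assert slope == pytest.approx(-0.5)
        assert intercept == pytest.approx(3.0)

    def test_constant_u(self):
        d = np.arange(10.0)
        u = np.full(10, 2.5)
        slope, intercept = linear_trend(np.column_stack([u, d]))
        assert slope == pytest.approx(0.0, abs=1e-12)
        assert intercept == pytest.approx(2.5)

    def test_matches_normal_equation_oracle(self, rng):
        d = rng.random(50) * 10
        u = rng.random(50)
        slope, intercept = linear_trend(np.column_stack([u, d]))
        # closed-form normal equations
        X = np.column_stack([d, np.ones(50)])
        beta = np.linalg.solve(X.T @ X, X.T @ u)
        assert slope == pytest.approx(beta[0])
        assert intercept == pytest.approx(beta[1])

    def test_degenerate_distance_error(self):
        pairs = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="degenerate"):
            linear_trend(pairs)


def test_binned_spearman_on_monotone_data(rng):
    d = rng.random(400) * 20
    u = np.exp(-d / 5) + rng.normal(0, 0.01, 400)
    h = joint_histogram(np.column_stack([u, d]), n_bins=10)
    res = binned_spearman(h)
    assert res is not None
    rho, _ = res
    assert rho < -0.9
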