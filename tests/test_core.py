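import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npcloud import (
    DimensionalityError,
    EmptyInputError,
    InsufficientPairsError,
    SearchRadii,
    cloud_mean,
    cloud_sigma,
    estimate_shift_iterative,
    pair_nearest,
    pair_nearest_bruteforce,
    simulate_two_channel,
)
from npcloud.core import DisplacementCloud

from conftest import grid_table


def assert_clouds_equal(a: DisplacementCloud, b: DisplacementCloud):
    np.testing.assert_array_equal(a.moving_index, b.moving_index)
    np.testing.assert_array_equal(a.reference_index, b.reference_index)
    np.testing.assert_array_equal(a.displacements, b.displacements)


class TestPairNearest:
    def test_identity_input_gives_zero_displacements(self, rng):
        pts = rng.uniform(0, 5000, size=(200, 2))
        cloud = pair_nearest(pts, pts)
        assert cloud.n_pairs == cloud.n_moving == 200
        np.testing.assert_array_equal(cloud.displacements, 0.0)

    def test_matches_bruteforce_on_hand_sized_input(self, rng):
        moving = rng.uniform(0, 300, size=(5, 2))
        reference = rng.uniform(0, 300, size=(7, 2))
        fast = pair_nearest(moving, reference)
        slow = pair_nearest_bruteforce(moving, reference)
        assert_clouds_equal(fast, slow)

    def test_all_displacements_respect_radius(self, rng):
        moving = rng.uniform(0, 2000, size=(300, 2))
        reference = rng.uniform(0, 2000, size=(300, 2))
        cloud = pair_nearest(moving, reference, SearchRadii(r_xy=40))
        d = cloud.displacements
        assert np.all(np.hypot(d[:, 0], d[:, 1]) <= 40)
        assert cloud.n_pairs <= cloud.n_moving

    def test_3d_cylindrical_gating(self, rng):
        moving = rng.uniform(0, 1000, size=(200, 3))
        reference = rng.uniform(0, 1000, size=(200, 3))
        radii = SearchRadii(r_xy=50, r_z=100)
        cloud = pair_nearest(moving, reference, radii)
        d = cloud.displacements
        assert np.all(np.hypot(d[:, 0], d[:, 1]) <= radii.r_xy)
        assert np.all(np.abs(d[:, 2]) <= radii.r_z)

    def test_3d_normalized_metric_prefers_radius_scaled_candidate(self):
        # Candidate A: lateral offset only; candidate B: axial offset only.
        # With r_xy=50, r_z=100, a 40 nm lateral offset scores 0.8 while an
        # 60 nm axial offset scores 0.6 — normalized picks B, Euclidean A.
        moving = np.array([[0.0, 0.0, 0.0]])
        reference = np.array([[40.0, 0.0, 0.0], [0.0, 0.0, 60.0]])
        radii = SearchRadii(r_xy=50, r_z=100)
        for fn in (pair_nearest, pair_nearest_bruteforce):
            assert fn(moving, reference, radii).reference_index[0] == 1
            assert fn(moving, reference, radii, metric="euclidean").reference_index[0] == 0

    def test_many_to_one_matching_allowed(self):
        moving = np.array([[0.0, 0.0], [1.0, 0.0]])
        reference = np.array([[0.5, 0.0]])
        cloud = pair_nearest(moving, reference, SearchRadii(r_xy=10))
        assert cloud.n_pairs == 2
        assert set(cloud.reference_index) == {0}

    def test_dimensionality_mismatch_raises(self, rng):
        with pytest.raises(DimensionalityError):
            pair_nearest(rng.uniform(size=(5, 2)), rng.uniform(size=(5, 3)))

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            pair_nearest(np.empty((0, 2)), np.ones((3, 2)))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**16), dim=st.sampled_from([2, 3]))
    def test_oracle_equivalence_fuzzed(self, seed, dim):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 200, size=2)
        span = 1500.0
        moving = rng.uniform(0, span, size=(n, dim))
        reference = rng.uniform(0, span, size=(m, dim))
        assert_clouds_equal(
            pair_nearest(moving, reference),
            pair_nearest_bruteforce(moving, reference),
        )


class TestCloudMean:
    def _cloud(self, disp):
        disp = np.asarray(disp, dtype=float)
        n = len(disp)
        return DisplacementCloud(
            disp, np.arange(n), np.arange(n), n, SearchRadii()
        )

    def test_symmetric_cloud_averages_to_zero(self):
        np.testing.assert_allclose(
            cloud_mean(self._cloud([[1, 1], [-1, -1]]), n_min=1), [0, 0]
        )

    def test_componentwise_arithmetic(self):
        np.testing.assert_allclose(
            cloud_mean(self._cloud([[3, 0], [0, 3], [3, 3]]), n_min=1), [2, 2]
        )

    def test_insufficient_pairs_error_carries_count(self):
        with pytest.raises(InsufficientPairsError) as exc:
            cloud_mean(self._cloud([[1, 1]] * 4), n_min=10)
        assert exc.value.n_pairs == 4

    def test_zero_shift_two_channel_mean_is_near_zero(self):
        # Two re-scattered copies of the same positions: the cloud mean
        # should sit within a few standard errors of the origin.
        red, blue = simulate_two_channel(density=1.0, sigma=10.0, seed=42)
        cloud = pair_nearest(red, blue)
        mean = cloud_mean(cloud)
        se = 10 * np.sqrt(2) / np.sqrt(cloud.n_pairs)
        assert np.all(np.abs(mean) <= 3 * se)


class TestIterativeEstimate:
    def test_identity_converges_to_zero_shift(self, rng):
        pts = rng.uniform(0, 5000, size=(300, 2))
        est = estimate_shift_iterative(pts, pts)
        assert est.converged
        np.testing.assert_allclose(est.shift, 0.0)

    def test_noiseless_separated_grid_recovers_shift_exactly(self):
        # Grid spacing far beyond 2*r_xy makes every nearest pairing the
        # true correspondence, so recovery is exact.
        reference = grid_table(spacing=200.0, n_side=12)
        shift = np.array([17.0, -23.0])
        moving = reference.with_coords(reference.coords + shift)
        est = estimate_shift_iterative(moving, reference, SearchRadii(r_xy=50))
        assert est.converged
        np.testing.assert_allclose(est.shift, shift, atol=1e-9)

    def test_shift_is_sum_of_retained_steps(self):
        red, blue = simulate_two_channel(
            density=1.0, sigma=10.0, shift=(20, 10), background_fold=9, seed=3
        )
        est = estimate_shift_iterative(red, blue)
        np.testing.assert_allclose(est.shift, np.sum(est.iterations, axis=0))

    def test_retained_step_magnitudes_strictly_decrease(self):
        red, blue = simulate_two_channel(
            density=1.0, sigma=10.0, shift=(20, 10), background_fold=9, seed=4
        )
        est = estimate_shift_iterative(red, blue)
        mags = [np.linalg.norm(s) for s in est.iterations]
        assert all(a > b for a, b in zip(mags, mags[1:]))

    def test_translation_equivariance_within_sampling_error(self):
        red, blue = simulate_two_channel(density=1.0, sigma=10.0, seed=5)
        base = estimate_shift_iterative(red, blue)
        v = np.array([8.0, -6.0])
        moved = red.with_coords(red.coords + v)
        shifted = estimate_shift_iterative(moved, blue)
        np.testing.assert_allclose(shifted.shift, base.shift + v, atol=1.5)

    def test_background_robustness(self):
        # Adding 9-fold uncorrelated background perturbs the converged
        # estimate by less than 3x the no-background standard error.
        shift = (20.0, 10.0)
        clean_r, clean_b = simulate_two_channel(
            density=1.0, sigma=10.0, shift=shift, background_fold=0, seed=6
        )
        noisy_r, noisy_b = simulate_two_channel(
            density=1.0, sigma=10.0, shift=shift, background_fold=9, seed=6
        )
        clean = estimate_shift_iterative(clean_r, clean_b)
        noisy = estimate_shift_iterative(noisy_r, noisy_b)
        se = 10 * np.sqrt(2) / np.sqrt(clean.n_pairs_final)
        assert np.linalg.norm(noisy.shift - clean.shift) < 3 * se * np.sqrt(2)

    def test_max_iter_reached_reports_not_converged(self):
        red, blue = simulate_two_channel(
            density=1.0, sigma=10.0, shift=(30, -20), background_fold=9, seed=7
        )
        est = estimate_shift_iterative(red, blue, max_iter=1)
        assert not est.converged
        assert len(est.iterations) == 1


class TestCloudStatistics:
    def test_pooled_width_is_root_two_sigma(self):
        # Independent sigma-10 scatter in each channel convolves to a
        # cloud of width sqrt(2)*10 per axis; assert within 5%.
        red, blue = simulate_two_channel(density=2.0, sigma=10.0, seed=8)
        cloud = pair_nearest(red, blue)
        assert cloud.n_pairs >= 1000
        sig = cloud_sigma(cloud)
        assert sig.pooled == pytest.approx(10 * np.sqrt(2), rel=0.05)
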