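import numpy as np
import pytest

from npcloud import (
    LocalizationTable,
    UndefinedShiftError,
    bin_localizations,
    dcc_drift,
    inject_drift,
    pairwise_correlation_count,
    rcc_drift,
    segment_frames,
    single_reference_correlation_count,
    xcorr_shift,
)
from npcloud.baselines import BinnedImage

from conftest import grid_table


class TestBinning:
    def test_single_localization_lands_in_its_bin(self):
        img = bin_localizations(
            np.array([[7.5, 7.5]]), grid_size=15, bounds=((0, 100), (0, 100))
        )
        assert img.counts[0, 0] == 1
        assert img.counts.sum() == 1

    def test_edge_value_goes_to_higher_bin(self):
        img = bin_localizations(
            np.array([[15.0, 0.0]]), grid_size=15, bounds=((0, 100), (0, 100))
        )
        assert img.counts[0, 1] == 1 and img.counts[0, 0] == 0

    def test_counts_are_conserved(self, rng):
        xy = rng.uniform(0, 1000, size=(1000, 2))
        img = bin_localizations(xy, grid_size=15, bounds=((0, 1000), (0, 1000)))
        assert img.counts.sum() == 1000

    def test_out_of_bounds_dropped(self):
        img = bin_localizations(
            np.array([[-5.0, 50.0], [50.0, 50.0]]),
            grid_size=15,
            bounds=((0, 100), (0, 100)),
        )
        assert img.counts.sum() == 1

    def test_empty_subset_with_bounds_is_all_zero(self):
        img = bin_localizations(
            np.empty((0, 2)), grid_size=15, bounds=((0, 100), (0, 100))
        )
        assert img.counts.sum() == 0


def _image_from_points(xy, bounds=((0, 3000), (0, 3000)), grid=15):
    return bin_localizations(np.asarray(xy, dtype=float), grid, bounds)


class TestXcorrShift:
    def test_autocorrelation_peak_at_zero_lag(self, rng):
        img = _image_from_points(rng.uniform(0, 3000, size=(500, 2)))
        np.testing.assert_allclose(xcorr_shift(img, img), [0.0, 0.0], atol=1e-9)

    def test_integer_bin_translation_recovered_exactly(self, rng):
        xy = rng.uniform(500, 2500, size=(400, 2))
        a = _image_from_points(xy + [30.0, 0.0])  # exactly 2 bins in x
        b = _image_from_points(xy)
        np.testing.assert_allclose(xcorr_shift(a, b), [30.0, 0.0], atol=1e-9)

    def test_non_integer_shift_recovered_within_half_grid(self, rng):
        xy = rng.uniform(500, 2500, size=(3000, 2))
        true = np.array([23.0, -11.0])
        a = _image_from_points(xy + true)
        b = _image_from_points(xy)
        est = xcorr_shift(a, b)
        assert np.all(np.abs(est - true) <= 7.5 + 1e-9)

    def test_antisymmetry(self, rng):
        xy = rng.uniform(500, 2500, size=(2000, 2))
        a = _image_from_points(xy + [23.0, 9.0])
        b = _image_from_points(xy)
        np.testing.assert_allclose(
            xcorr_shift(a, b), -xcorr_shift(b, a), atol=2.0
        )

    def test_all_zero_image_raises(self):
        zero = _image_from_points(np.empty((0, 2)))
        with pytest.raises(UndefinedShiftError):
            xcorr_shift(zero, zero)

    def test_mismatched_grids_raise(self, rng):
        a = _image_from_points(rng.uniform(0, 3000, size=(50, 2)))
        b = bin_localizations(
            rng.uniform(0, 3000, size=(50, 2)), 30, ((0, 3000), (0, 3000))
        )
        with pytest.raises(ValueError):
            xcorr_shift(a, b)


def _repeated_grid_dataset(n_segments=4, L=10, drift_per_segment=(30.0, -15.0)):
    """Dense noiseless data with integer-bin per-segment drift: DCC must be
    exact."""
    base = grid_table(spacing=105.0, n_side=14)
    per_segment = np.array(
        [np.array(drift_per_segment) * k for k in range(n_segments)]
    )
    parts = []
    for seg in range(n_segments):
        for f in range(seg * L + 1, (seg + 1) * L + 1):
            parts.append(
                LocalizationTable(
                    x=base.x + per_segment[seg][0],
                    y=base.y + per_segment[seg][1],
                    frame=np.full(base.n, f, np.int64),
                )
            )
    return (
        LocalizationTable(
            x=np.concatenate([p.x for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            frame=np.concatenate([p.frame for p in parts]),
        ),
        per_segment,
    )


class TestDccDrift:
    def test_integer_bin_drift_recovered_exactly(self):
        table, per_segment = _repeated_grid_dataset()
        trace = dcc_drift(table, 10, grid_size=15)
        np.testing.assert_allclose(trace.segment_drift, per_segment, atol=1e-6)

    def test_zero_drift_clustered_data_within_one_bin(self):
        # Segments of a drift-free clustered acquisition share structure,
        # so every cross-correlation peak sits within one grid cell of zero.
        from npcloud import SimulationConfig, simulate_clusters

        cfg = SimulationConfig(
            n_frames=100, cluster_density=50, field_size=5, seed=44
        )
        table, _ = simulate_clusters(cfg)
        trace = dcc_drift(table, 25, grid_size=15)
        assert np.abs(trace.segment_drift).max() <= 15.0


class TestRccDrift:
    def test_consistent_pairwise_shifts_reproduced_exactly(self):
        table, per_segment = _repeated_grid_dataset(n_segments=3)
        trace = rcc_drift(table, 10, grid_size=15)
        np.testing.assert_allclose(trace.segment_drift, per_segment, atol=1e-6)

    def test_matches_dcc_on_consistent_data(self):
        table, _ = _repeated_grid_dataset(n_segments=4)
        np.testing.assert_allclose(
            rcc_drift(table, 10).segment_drift,
            dcc_drift(table, 10).segment_drift,
            atol=1e-6,
        )

    def test_corrupted_pair_rejected_by_outlier_pass(self, monkeypatch):
        import npcloud.baselines as bl

        # 6 segments -> 15 redundant pairs: one corrupted estimate leaves
        # the good pairs' post-fit residuals under the rejection threshold.
        table, per_segment = _repeated_grid_dataset(n_segments=6)
        real = bl.xcorr_shift
        calls = {"i": 0}

        def corrupting(a, b, max_lag=bl.DEFAULT_MAX_LAG):
            out = real(a, b, max_lag)
            calls["i"] += 1
            if calls["i"] == 2:  # corrupt exactly one pairwise estimate
                return out + np.array([150.0, 0.0])
            return out

        monkeypatch.setattr(bl, "xcorr_shift", corrupting)
        trace = bl.rcc_drift(table, 10, grid_size=15)
        np.testing.assert_allclose(trace.segment_drift, per_segment, atol=1e-6)

    def test_correlation_count_ratio_for_660_segments(self):
        assert pairwise_correlation_count(660) == 660 * 659 // 2
        assert (
            pairwise_correlation_count(660)
            / single_reference_correlation_count(660)
            == 330
        )
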