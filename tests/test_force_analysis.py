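"""Threshold, corrected high-force fraction, ASH and force-PDF subtraction."""

import numpy as np
import pytest

from smforce import (
    SensorCalibration,
    ash_pdf,
    bootstrap_fraction,
    compute_threshold,
    efficiency_from_force,
    estimate_force_pdf,
    high_force_fraction,
    sturges_bins,
)


class TestComputeThreshold:
    def test_interpolated_quantile_on_integers(self):
        # values 1..100 at f=0.05: numpy's linear rule gives
        # 1 + 0.05 * 99 = 5.95, between the 5th and 6th order statistics
        thr = compute_threshold(np.arange(1, 101, dtype=float), f=0.05)
        assert thr.q_f == pytest.approx(5.95)
        assert 5.0 < thr.q_f < 6.0

    def test_degenerate_distribution(self):
        thr = compute_threshold(np.full(50, 0.7), f=0.05)
        assert thr.q_f == pytest.approx(0.7)

    def test_uniform_sample(self, rng):
        thr = compute_threshold(rng.random(100_000), f=0.05)
        assert thr.q_f == pytest.approx(0.05, abs=0.005)

    def test_too_few_points_error_names_minimum(self):
        with pytest.raises(ValueError, match="20"):
            compute_threshold(np.arange(10, dtype=float))

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            compute_threshold(np.arange(100, dtype=float), f=1.5)


class TestHighForceFraction:
    def test_null_case_near_zero(self, rng):
        thr = compute_threshold(rng.normal(0.865, 0.164, 50_000), f=0.05)
        res = high_force_fraction(rng.normal(0.865, 0.164, 50_000), thr)
        se = np.sqrt(0.05 * 0.95 / 50_000)
        assert abs(res.fraction_point) < 3 * se

    def test_saturated_case(self):
        thr = compute_threshold(np.linspace(0.5, 1.0, 100), f=0.05)
        res = high_force_fraction(np.full(200, 0.1), thr)
        assert res.fraction_point == pytest.approx(0.95)

    def test_mixture_recovers_095_phi(self, rng):
        # phi of datapoints far below threshold: expectation 0.95 * phi
        phi, n = 0.10, 100_000
        thr = compute_threshold(rng.normal(0.865, 0.164, n), f=0.05)
        forced = rng.random(n) < phi
        cell = np.where(forced, rng.normal(0.1444, 0.164, n),
                        rng.normal(0.865, 0.164, n))
        res = high_force_fraction(cell, thr)
        assert res.fraction_point == pytest.approx(0.95 * phi, abs=0.01)

    def test_negative_fractions_not_clamped(self):
        thr = compute_threshold(np.linspace(0.0, 1.0, 1000), f=0.05)
        res = high_force_fraction(np.full(100, 0.5), thr)
        assert res.fraction_point == pytest.approx(-0.05)

    def test_empty_input_errors(self):
        thr = compute_threshold(np.linspace(0, 1, 100))
        with pytest.raises(ValueError):
            high_force_fraction(np.array([]), thr)


class TestBootstrapFraction:
    def test_identical_tracks_degenerate(self):
        thr = compute_threshold(np.linspace(0.5, 1.0, 100), f=0.05)
        tracks = [np.array([0.1, 0.9])] * 10
        res = bootstrap_fraction(tracks, thr, n_boot=100, seed=0)
        assert res.bootstrap.se == pytest.approx(0.0)
        assert res.bootstrap.median == pytest.approx(res.fraction_point)

    def test_seed_determinism(self, mixture_dataset, no_cell_dataset):
        thr = compute_threshold(
            no_cell_dataset.data["efficiency"].to_numpy(), f=0.05
        )
        tracks = mixture_dataset.track_values("efficiency")
        a = bootstrap_fraction(tracks, thr, n_boot=200, seed=5)
        b = bootstrap_fraction(tracks, thr, n_boot=200, seed=5)
        assert a.bootstrap == b.bootstrap

    def test_mixture_mean_recovery(self, rng):
        phi = 0.10
        thr = compute_threshold(rng.normal(0.865, 0.164, 50_000), f=0.05)
        tracks = []
        for i in range(200):
            mu = 0.1444 if i < 20 else 0.865
            tracks.append(rng.normal(mu, 0.164, 10))
        res = bootstrap_fraction(tracks, thr, n_boot=400, seed=1)
        assert abs(res.bootstrap.mean - 0.95 * phi) < 3 * res.bootstrap.se

    def test_quartiles_ordered(self, rng):
        thr = compute_threshold(rng.normal(0.865, 0.164, 10_000), f=0.05)
        tracks = [rng.normal(0.865, 0.164, 5) for _ in range(50)]
        bs = bootstrap_fraction(tracks, thr, n_boot=300, seed=2).bootstrap
        assert (bs.whisker_lo <= bs.q1 <= bs.median <= bs.q3 <= bs.whisker_hi)

    def test_convergence_of_summaries(self, rng):
        thr = compute_threshold(rng.normal(0.865, 0.164, 10_000), f=0.05)
        tracks = [rng.normal(0.865, 0.164, 8) for _ in range(80)]
        small = bootstrap_fraction(tracks, thr, n_boot=1000, seed=3).bootstrap
        large = bootstrap_fraction(tracks, thr, n_boot=4000, seed=4).bootstrap
        assert abs(small.median - large.median) < small.se

    def test_requires_enough_tracks_and_resamples(self):
        thr = compute_threshold(np.linspace(0, 1, 100))
        with pytest.raises(ValueError):
            bootstrap_fraction([np.array([0.5])], thr)
        with pytest.raises(ValueError):
            bootstrap_fraction([np.array([0.5]), np.array([0.6])], thr, n_boot=1)


class TestAshPdf:
    def test_sturges_bin_counts(self):
        assert sturges_bins(1000) == 11
        assert sturges_bins(2) == 2

    def test_normalization(self, rng):
        grid, dens = ash_pdf(rng.normal(0.0, 1.0, 5000), -0.5, 1.5)
        delta = grid[1] - grid[0]
        assert dens.sum() * delta == pytest.approx(1.0, abs=1e-6)
        assert np.all(dens >= 0)

    def test_grid_resolution(self, rng):
        grid, _ = ash_pdf(rng.random(1000), -0.5, 1.5, n_shifts=40,
                          n_points_for_bins=1000)
        assert len(grid) == 11 * 40
        assert grid[0] > -0.5 and grid[-1] < 1.5

    def test_out_of_range_values_excluded(self, rng):
        vals = np.r_[rng.random(1000), np.full(100, 7.0)]
        grid, dens = ash_pdf(vals, -0.5, 1.5)
        delta = grid[1] - grid[0]
        assert dens.sum() * delta == pytest.approx(1.0, abs=1e-6)

    def test_peak_location_tracks_sample_mode(self, rng):
        grid, dens = ash_pdf(rng.normal(0.865, 0.164, 20_000), -0.5, 1.5)
        assert grid[np.argmax(dens)] == pytest.approx(0.865, abs=0.05)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ash_pdf(np.array([]))


class TestEstimateForcePdf:
    def _mixture(self, rng, phi, force_pN, n, calib):
        mu_f = efficiency_from_force(force_pN, calib)
        forced = rng.random(n) < phi
        return np.where(forced, rng.normal(mu_f, 0.164, n),
                        rng.normal(0.865, 0.164, n))

    def test_self_subtraction_detects_no_force(self, rng):
        sample = rng.normal(0.865, 0.164, 20_000)
        pdf = estimate_force_pdf(sample, sample)
        assert pdf.no_force_detected
        assert pdf.median is None

    def test_median_recovers_injected_force(self, rng, calib):
        medians = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            cell = self._mixture(r, 0.2, 5.0, 20_000, calib)
            nocell = r.normal(0.865, 0.164, 20_000)
            pdf = estimate_force_pdf(cell, nocell, calib)
            assert not pdf.no_force_detected
            medians.append(pdf.median)
        assert np.all(np.abs(np.asarray(medians) - 5.0) < 0.5)

    def test_scale_parameters_recover_mixture_weight(self, rng, calib):
        phi = 0.2
        cell = self._mixture(rng, phi, 9.0, 40_000, calib)
        nocell = rng.normal(0.865, 0.164, 40_000)
        pdf = estimate_force_pdf(cell, nocell, calib)
        assert pdf.s_width == pytest.approx(1.0, abs=0.05)
        assert pdf.s_height == pytest.approx(1 - phi, abs=0.05)

    def test_density_nonnegative_and_quartiles_ordered(self, rng, calib):
        cell = self._mixture(rng, 0.15, 5.0, 15_000, calib)
        nocell = rng.normal(0.865, 0.164, 15_000)
        pdf = estimate_force_pdf(cell, nocell, calib)
        assert np.all(pdf.density >= 0)
        assert pdf.q1 <= pdf.median <= pdf.q3
        assert pdf.force_grid[0] <= pdf.q1 and pdf.q3 <= pdf.force_grid[-1]

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            estimate_force_pdf(np.array([]), np.array([0.5]))
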