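import numpy as np
import pytest

from thetanet import analysis
from thetanet.analysis import (
    CrossCorrHistogram,
    circlin_fit,
    classify_pairs,
    corr_bin_edges,
    correlation_lag,
    cross_correlogram,
    ex_in,
    fit_precession,
    gradient_map,
    spike_phase,
    theta_compression,
)
from thetanet.synthetic import (
    lagged_pair,
    poisson_train,
    precessing_spikes,
    timed_grid_record,
)


class TestSpikePhase:
    def test_reference_points(self):
        assert spike_phase(0.0) == 0.0
        assert spike_phase(250.0) == pytest.approx(np.pi)
        t_mec_peak = 70.0 / 360.0 * 100.0
        assert spike_phase(t_mec_peak) == pytest.approx(np.deg2rad(70.0))


class TestCirclinFit:
    @pytest.mark.parametrize("slope", [-2 * np.pi, -np.pi, -0.5, 0.0, 1.0, 2 * np.pi])
    def test_recovers_noiseless_slope(self, slope):
        x = np.linspace(0, 1, 40)
        phases = np.mod(1.0 + slope * x, 2 * np.pi)
        a, onset, R = circlin_fit(phases, x, (-4 * np.pi, 4 * np.pi))
        assert a == pytest.approx(slope, abs=0.1)
        assert R > 0.99

    def test_onset_is_circular_intercept(self):
        x = np.linspace(0, 1, 20)
        phases = np.mod(2.5 - 1.3 * x, 2 * np.pi)
        a, onset, _ = circlin_fit(phases, x, (-4 * np.pi, 4 * np.pi))
        assert onset == pytest.approx(2.5, abs=0.05)


class TestFitPrecession:
    def test_generator_ground_truth(self):
        t, pos = precessing_spikes(slope=-np.pi, onset=0.0, n_spikes=6)
        fit = fit_precession(t, pos)
        assert fit.slope == pytest.approx(-np.pi, abs=0.1)
        assert min(fit.onset, 2 * np.pi - fit.onset) == pytest.approx(0.0, abs=0.1)

    def test_constant_phase_gives_zero_slope(self):
        t = np.arange(6) * 100.0 + 20.0  # same phase every cycle
        pos = np.linspace(0, 10, 6)
        fit = fit_precession(t, pos)
        assert fit.slope == pytest.approx(0.0, abs=1e-6)
        assert fit.rho == pytest.approx(0.0, abs=1e-6)

    def test_too_few_spikes_excluded(self):
        assert fit_precession([1, 2, 3, 4, 5], [0, 1, 2, 3, 4]) is None

    @pytest.mark.parametrize("slope", np.linspace(-2 * np.pi, 2 * np.pi, 7))
    def test_slope_recovery_across_range(self, slope):
        t, pos = precessing_spikes(slope=slope, onset=1.0, n_spikes=25)
        fit = fit_precession(t, pos)
        assert fit.slope == pytest.approx(slope, abs=0.1)


class TestCrossCorrelogram:
    def test_autocorrelation_peaks_at_zero(self):
        train = poisson_train(30.0, 2000.0, seed=1)
        h = cross_correlogram(train, train)
        centers = h.bin_centers
        zero_bins = np.argsort(np.abs(centers))[:2]
        assert h.counts.argmax() in zero_bins

    def test_single_pair_lands_in_correct_bin(self):
        h = cross_correlogram([100.0], [120.0])
        k = h.counts.argmax()
        assert h.counts.sum() == 1
        assert h.bin_edges[k] == 20.0
        assert h.bin_edges[k + 1] == 25.0

    def test_bin_width_exactly_5ms_spanning_window(self):
        edges = corr_bin_edges()
        assert len(edges) == 41
        assert np.all(np.diff(edges) == 5.0)
        assert edges[0] == -100.0 and edges[-1] == 100.0

    def test_poisson_pair_is_flat(self):
        a = poisson_train(20.0, 2000.0, seed=2)
        b = poisson_train(20.0, 2000.0, seed=3)
        h = cross_correlogram(a, b)
        expected = len(a) * len(b) * 5.0 / 2000.0
        sigma = np.sqrt(expected)
        assert np.all(np.abs(h.counts - expected) < 3.5 * sigma)

    def test_empty_train_flagged(self):
        h = cross_correlogram([], [1.0, 2.0])
        assert h.empty
        assert not h.counts.any()


class TestCorrelationLag:
    def _hist(self, f):
        centers = corr_bin_edges()[:-1] + 2.5
        return f(centers / 1000.0)

    def test_even_cosine_has_zero_phase(self):
        counts = self._hist(lambda t: np.cos(2 * np.pi * 8.0 * t))
        assert correlation_lag(counts) == pytest.approx(0.0, abs=0.03)

    def test_shifted_cosine_phase(self):
        counts = self._hist(lambda t: np.cos(2 * np.pi * 8.0 * (t - 0.015)))
        assert correlation_lag(counts) == pytest.approx(-2 * np.pi * 8 * 0.015, abs=0.05)

    def test_time_reversal_negates_phase(self):
        counts = self._hist(lambda t: np.cos(2 * np.pi * 8.0 * (t - 0.012)) + 1.2)
        assert correlation_lag(counts[::-1]) == pytest.approx(
            -correlation_lag(counts), abs=0.05
        )

    def test_bin_shift_equivariance(self):
        counts = self._hist(lambda t: np.cos(2 * np.pi * 8.0 * t) + 1.0)
        shifted = np.roll(counts, 1)
        dphi = correlation_lag(shifted) - correlation_lag(counts)
        assert dphi == pytest.approx(-2 * np.pi * 8.0 * 0.005, abs=0.05)

    def test_empty_histogram_undefined(self):
        assert np.isnan(correlation_lag(np.zeros(40)))

    def test_recovers_lag_from_spike_trains(self):
        a, b = lagged_pair(lag_ms=15.0, n_cycles=20)
        # first-encountered = a, next = b: histogram of t_a - t_b
        h = cross_correlogram(b, a)
        phase = correlation_lag(h)
        # mass at -15 ms -> positive analytic phase ~ 2 pi f 0.015
        assert phase == pytest.approx(2 * np.pi * 10.0 * 0.015, abs=0.25)


class TestExIn:
    def test_identical_symmetric_histograms(self):
        h = np.array([0.0, 1, 2, 4, 2, 1] + [0.0] * 34)
        sym = (h + h[::-1])
        ex, inn = ex_in(sym, sym)
        assert ex == pytest.approx(1.0)
        assert inn == pytest.approx(1.0)

    def test_flipped_pair_is_intrinsic(self):
        h = np.zeros(40)
        h[25:29] = [1, 3, 2, 1]
        ex, inn = ex_in(h, h[::-1])
        assert inn == pytest.approx(1.0)
        assert ex < 1.0

    def test_hand_computed_toy_vectors(self):
        h1 = np.zeros(40)
        h1[:6] = [0, 1, 2, 1, 0, 0]
        ex, inn = ex_in(h1, h1)
        assert ex == pytest.approx(1.0)
        ex2, inn2 = ex_in(h1, h1[::-1])
        assert inn2 == pytest.approx(1.0)
        # pearson of h1 with its own flip, hand-computed
        r = np.corrcoef(h1, h1[::-1])[0, 1]
        assert ex2 == pytest.approx((r + 1) / 2)

    def test_zero_variance_undefined(self):
        ex, inn = ex_in(np.ones(40), np.zeros(40) + 2.0)
        assert np.isnan(ex) and np.isnan(inn)

    def test_swap_symmetry_of_extrinsicity(self):
        rng = np.random.default_rng(0)
        h1, h2 = rng.poisson(3.0, 40).astype(float), rng.poisson(3.0, 40).astype(float)
        ex_ab, _ = ex_in(h1, h2)
        ex_ba, _ = ex_in(h2, h1)
        assert ex_ab == pytest.approx(ex_ba)
        # Ex invariant under simultaneous flip of both histograms
        ex_ff, _ = ex_in(h1[::-1], h2[::-1])
        assert ex_ff == pytest.approx(ex_ab)


class TestThetaCompression:
    def test_recovers_generator_slope(self):
        d = np.linspace(2, 10, 30)
        a, phi0, n = theta_compression(0.2 * d, d)
        assert a == pytest.approx(0.2, abs=0.01)
        assert n == 30

    def test_zero_lags_zero_slope(self):
        d = np.linspace(2, 10, 10)
        a, _, _ = theta_compression(np.zeros(10), d)
        assert a == pytest.approx(0.0, abs=1e-6)

    def test_too_few_pairs_undefined(self):
        a, phi0, n = theta_compression([0.1, 0.2], [1.0, 2.0])
        assert np.isnan(a)


class TestClassifyPairs:
    def test_aligned_pair_is_best_and_similar(self):
        bw, sim = classify_pairs(0.0, 0.0, 0.0)
        assert bw[0] == "both-best" and sim[0] == "similar"

    def test_opposed_pair_is_dissimilar_only(self):
        bw, sim = classify_pairs(0.0, np.pi, 0.0)
        assert bw[0] == "other" and sim[0] == "dissimilar"

    def test_140_degree_difference_is_other(self):
        bw, sim = classify_pairs(np.deg2rad(20), np.deg2rad(160), 0.0)
        assert sim[0] == "other"

    def test_worst_pair(self):
        bw, _ = classify_pairs(np.deg2rad(170), np.deg2rad(-170), 0.0)
        assert bw[0] == "both-worst"


class TestGradientMap:
    def test_linear_time_field_points_along_x(self):
        rec = timed_grid_record(lambda x, y: x, n_side=8, window_start=500.0)
        arrows, valid = gradient_map(rec, (500.0 - 50.0, 600.0))
        grid = rec.grids["CA3"]
        # interior cells (all 8 neighbours present); edge cells pick up
        # asymmetric diagonal contributions
        half = grid.arena.width / 2 - 1.5 * grid.spacing
        interior = valid & np.all(np.abs(grid.centers) < half, axis=1)
        assert interior.any()
        angles = np.arctan2(arrows[interior, 1], arrows[interior, 0])
        assert np.allclose(np.cos(angles), 1.0, atol=1e-9)

    def test_uniform_times_zero_arrows(self):
        rec = timed_grid_record(lambda x, y: 0.0, n_side=6, window_start=0.0)
        arrows, valid = gradient_map(rec, (0.0, 100.0))
        assert valid.any()
        assert np.allclose(arrows[valid], 0.0)

    def test_radial_times_point_outward(self):
        rec = timed_grid_record(lambda x, y: np.hypot(x, y), n_side=10)
        arrows, valid = gradient_map(rec, (0.0, 200.0))
        grid = rec.grids["CA3"]
        centers = grid.centers[valid]
        away = centers / np.maximum(np.linalg.norm(centers, axis=1), 1e-9)[:, None]
        dots = np.sum(arrows[valid] * away, axis=1)
        interior = np.linalg.norm(centers, axis=1) > grid.spacing
        assert np.all(dots[interior] > 0)
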