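"""Spectral decomposition, classification and circular statistics."""

import math

import numpy as np
import pytest

from chronospeckle import rhythm, simulate
from chronospeckle.rhythm import (
    CIRCADIAN,
    ULTRADIAN12,
    SpectralComponent,
    acrophase,
    classify_component,
    classify_series,
    detrend_polynomial,
    dominant_component,
    matrix_pencil_decompose,
    periodogram_psd,
    permutation_fdr,
    phase_distribution,
    reconstruct,
)
from chronospeckle.timeseries import TimeSeries


# ---------------------------------------------------------------- detrend
class TestDetrend:
    def test_exact_polynomial_leaves_zero_residual(self, grid_48h):
        t = grid_48h
        ts = TimeSeries(t, 3 * t**2 + 2 * t + 1)
        trend, resid = detrend_polynomial(ts, 2)
        np.testing.assert_allclose(resid.values, 0.0, atol=1e-9)
        np.testing.assert_allclose(trend.values + resid.values, ts.values)

    def test_linear_series_degree_one(self, grid_48h):
        ts = TimeSeries(grid_48h, 5.0 - 0.3 * grid_48h)
        _, resid = detrend_polynomial(ts, 1)
        np.testing.assert_allclose(resid.values, 0.0, atol=1e-9)

    def test_is_projection(self, grid_48h):
        rng = np.random.default_rng(3)
        ts = TimeSeries(grid_48h, rng.normal(size=grid_48h.size))
        _, once = detrend_polynomial(ts, 2)
        _, twice = detrend_polynomial(once, 2)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_removes_drift_revealing_oscillation(self):
        t = 2.0 * np.arange(48)
        ts = TimeSeries(t, np.cos(2 * np.pi * t / 12.0) + 0.5 * t)
        _, resid = detrend_polynomial(ts, 1)
        _, _, peak = periodogram_psd(resid)
        assert peak == pytest.approx(12.0, rel=0.05)

    def test_degree_too_high_raises(self):
        ts = TimeSeries([0.0, 1.0, 2.0], [1, 2, 3])
        with pytest.raises(ValueError):
            detrend_polynomial(ts, 2)


# ---------------------------------------------------------------- pencil
class TestMatrixPencil:
    def test_constant_series_is_single_dc_component(self, grid_48h):
        comps = matrix_pencil_decompose(TimeSeries(grid_48h, np.full(24, 5.0)))
        assert len(comps) == 1
        assert not comps[0].is_oscillatory
        assert comps[0].amplitude == pytest.approx(5.0)

    def test_pure_cosine_recovery(self, cos12):
        comps = matrix_pencil_decompose(cos12)
        osc = [c for c in comps if c.is_oscillatory]
        assert len(osc) == 1
        assert osc[0].period == pytest.approx(12.0, abs=0.01)
        assert osc[0].decay_per_sample == pytest.approx(1.0, abs=0.001)
        assert osc[0].amplitude == pytest.approx(1.0, abs=0.01)

    def test_two_component_damped_mixture(self, grid_48h):
        t = grid_48h
        k = np.arange(t.size)
        x = 0.95**k * np.cos(2 * np.pi * t / 24.0) + 0.5 * np.cos(2 * np.pi * t / 12.0)
        ts = TimeSeries(t, x)
        comps = matrix_pencil_decompose(ts)
        rec = reconstruct(comps, t, 2.0)
        assert np.max(np.abs(rec - x)) < 1e-6 * np.max(np.abs(x))
        osc = sorted((c for c in comps if c.is_oscillatory), key=lambda c: c.period)
        assert [round(c.period, 1) for c in osc] == [12.0, 24.0]
        assert osc[0].decay_per_sample == pytest.approx(1.0, rel=0.01)
        assert osc[1].decay_per_sample == pytest.approx(0.95, rel=0.01)

    def test_phase_recovery(self, grid_48h):
        t = grid_48h
        ts = TimeSeries(t, np.cos(2 * np.pi * t / 12.0 + 1.0))
        dom = dominant_component(matrix_pencil_decompose(ts))
        assert dom.phase == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("n_comp", [1, 2, 3])
    def test_reconstruction_invariant(self, n_comp):
        """Noiseless series with few components reconstruct to < 1e-6."""
        rng = np.random.default_rng(10 + n_comp)
        t = 2.0 * np.arange(24)
        k = np.arange(24)
        periods = rng.choice([8.0, 12.0, 24.0, 16.0], size=n_comp, replace=False)
        x = np.zeros(24)
        for T in periods:
            x += rng.uniform(0.5, 2) * rng.uniform(0.9, 1.0) ** k * np.cos(
                2 * np.pi * t / T + rng.uniform(-np.pi, np.pi)
            )
        comps = matrix_pencil_decompose(TimeSeries(t, x))
        rec = reconstruct(comps, t, 2.0)
        assert np.max(np.abs(rec - x)) < 1e-6 * np.max(np.abs(x))

    def test_noisy_period_recovery_median_under_5pct(self):
        """12-h component on the 48-h/2-h design, 10%-of-amplitude noise."""
        errs = []
        for seed in range(100):
            scen = simulate.SimScenario(noise_sd=0.1, seed=seed)
            ts = simulate.gen_damped_sinusoid([simulate.ComponentSpec(1.0, 12.0)], scen)
            dom = dominant_component(matrix_pencil_decompose(ts))
            errs.append(abs(dom.period - 12.0) / 12.0)
        assert np.median(errs) < 0.05

    def test_non_uniform_sampling_rejected(self):
        ts = TimeSeries([0.0, 1.0, 3.0, 4.0, 6.0], [1, 2, 1, 2, 1])
        with pytest.raises(ValueError, match="uniform"):
            matrix_pencil_decompose(ts)


# ---------------------------------------------------------------- labels
class TestClassification:
    def test_dominant_prefers_largest_amplitude(self):
        c24 = SpectralComponent(2.0, 24.0, 1.0, 0.0)
        c12 = SpectralComponent(1.0, 12.0, 1.0, 0.0)
        dc = SpectralComponent(10.0, math.inf, 1.0, 0.0)
        assert dominant_component([dc, c12, c24]) is c24

    def test_dominant_tie_breaks_to_shorter_period(self):
        c24 = SpectralComponent(1.0, 24.0, 1.0, 0.0)
        c12 = SpectralComponent(1.0, 12.0, 1.0, 0.0)
        assert dominant_component([c24, c12]) is c12

    def test_dominant_none_without_oscillation(self):
        assert dominant_component([SpectralComponent(1.0, math.inf, 1.0, 0.0)]) is None

    @pytest.mark.parametrize(
        "period, decay, expected",
        [
            (23.0, 1.0, "circadian"),
            (12.0, 1.0, "ultradian12"),
            (12.0, 0.5, "other"),  # decay window violated
            (13.5, 0.8, "ultradian12"),  # endpoints inclusive
            (10.5, 1.2, "ultradian12"),
            (21.0, 0.8, "circadian"),
            (25.0, 1.2, "circadian"),
            (20.99, 1.0, "other"),
            (25.01, 1.0, "other"),
            (13.51, 1.0, "other"),
            (18.0, 1.0, "other"),
            (12.0, 1.21, "other"),
        ],
    )
    def test_window_grid(self, period, decay, expected):
        c = SpectralComponent(1.0, period, decay, 0.0)
        assert classify_component(c) == expected

    def test_labels_partition_parameter_space(self):
        """Every (period, decay) point gets exactly one label."""
        for period in np.linspace(2, 40, 39):
            for decay in np.linspace(0.0, 2.0, 21):
                label = classify_component(SpectralComponent(1.0, period, decay, 0.0))
                assert label in {"circadian", "ultradian12", "other"}
                in_circ = 21 <= period <= 25 and 0.8 <= decay <= 1.2
                in_ultra = 10.5 <= period <= 13.5 and 0.8 <= decay <= 1.2
                assert (label == "circadian") == in_circ
                assert (label == "ultradian12") == in_ultra


# ---------------------------------------------------------------- PSD
class TestPeriodogram:
    def test_pure_cosine_peak(self):
        t = 2.0 * np.arange(48)  # 96 h so the grid contains 1/12
        ts = TimeSeries(t, np.cos(2 * np.pi * t / 12.0))
        _, _, peak = periodogram_psd(ts)
        assert peak == pytest.approx(12.0)

    def test_constant_series_has_no_peak(self, grid_48h):
        freqs, power, peak = periodogram_psd(TimeSeries(grid_48h, np.full(24, 3.0)))
        assert peak is None
        np.testing.assert_allclose(power[freqs > 0], 0.0, atol=1e-25)

    def test_white_noise_peak_not_persistent(self):
        """No frequency dominates across independent noise realizations."""
        t = 2.0 * np.arange(48)
        peaks = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            _, _, peak = periodogram_psd(TimeSeries(t, rng.normal(size=48)))
            peaks.append(peak)
        # the modal peak period should not account for most runs
        _, counts = np.unique(np.round(peaks, 3), return_counts=True)
        assert counts.max() <= len(peaks) // 2


# ---------------------------------------------------------------- FDR
class TestPermutationFdr:
    def _rhythm_set(self, n=8):
        out = []
        rng = np.random.default_rng(5)
        for i in range(n):
            scen = simulate.SimScenario(dt=1.0, n_samples=48, noise_sd=0.05, seed=50 + i)
            out.append(
                simulate.gen_damped_sinusoid(
                    [simulate.ComponentSpec(1.0, 12.0, 1.0, rng.uniform(-np.pi, np.pi))],
                    scen,
                )
            )
        return out

    def test_no_observed_calls_gives_fdr_one(self, grid_48h):
        flat = [TimeSeries(grid_48h, np.full(24, float(i))) for i in range(3)]
        assert permutation_fdr(flat, "ultradian12", B=100, seed=0) == 1.0

    def test_strong_rhythms_give_low_fdr(self):
        fdr = permutation_fdr(self._rhythm_set(), "ultradian12", B=200, seed=1)
        assert fdr < 0.1

    def test_deterministic_and_order_invariant(self):
        series = self._rhythm_set(5)
        a = permutation_fdr(series, "ultradian12", B=100, seed=9)
        b = permutation_fdr(series, "ultradian12", B=100, seed=9)
        c = permutation_fdr(series[::-1], "ultradian12", B=100, seed=9)
        assert a == b == c

    def test_requires_enough_permutations(self, cos12):
        with pytest.raises(ValueError):
            permutation_fdr([cos12], "ultradian12", B=50, seed=0)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            permutation_fdr([], "ultradian12", B=100, seed=0)


# ---------------------------------------------------------------- phase
class TestPhase:
    @pytest.mark.parametrize(
        "phi, period, expected",
        [(0.0, 12.0, 0.0), (math.pi, 12.0, 6.0), (-math.pi / 2, 12.0, 3.0)],
    )
    def test_acrophase_formula(self, phi, period, expected):
        c = SpectralComponent(1.0, period, 1.0, phi)
        assert acrophase(c) == pytest.approx(expected)

    def test_acrophase_marks_the_series_maximum(self, grid_48h):
        t = grid_48h
        ts = TimeSeries(t, np.cos(2 * np.pi * (t - 4.0) / 12.0))
        dom = dominant_component(matrix_pencil_decompose(ts))
        assert acrophase(dom) == pytest.approx(4.0, abs=0.01)

    def test_single_phase_cluster(self):
        dist = phase_distribution([8.0] * 10, 12.0)
        assert dist.circular_mean == pytest.approx(8.0)
        assert dist.resultant_length == pytest.approx(1.0)

    def test_antipodal_peaks_cancel(self):
        dist = phase_distribution([0.0, 6.0], 12.0)
        assert dist.resultant_length == pytest.approx(0.0, abs=1e-12)

    def test_uniform_peaks_have_small_resultant(self):
        rng = np.random.default_rng(11)
        dist = phase_distribution(rng.uniform(0, 12, 2000), 12.0)
        assert dist.resultant_length < 0.05


def test_classify_series_end_to_end(cos12):
    call = classify_series(cos12)
    assert call.label == "ultradian12"
    assert call.dominant.period == pytest.approx(12.0, abs=0.01)


def test_decay_per_hour_conversion():
    assert rhythm.decay_per_hour(0.81, 2.0) == pytest.approx(0.9)
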