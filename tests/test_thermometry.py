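"""PRF coefficient, gated/free reconstructions, baseline library, gating."""

import numpy as np
import pytest

import thermodose as td
from thermodose.containers import wrap_phase
from thermodose.errors import ConfigurationError, UsageError
from thermodose.thermometry import (
    PRFModel,
    build_baseline_library,
    default_background_mask,
    phase_to_temperature_coefficient,
    reconstruct_free_breathing,
    reconstruct_gated,
)


def geometry(**kw):
    base = dict(n_slices=6, n_rows=20, n_cols=20)
    base.update(kw)
    return td.AcquisitionGeometry(**base)


def make_series(phases, geometry, magnitude=None):
    phases = np.asarray(phases)
    mag = np.ones_like(phases) if magnitude is None else magnitude
    return td.ComplexVolumeSeries(
        mag, wrap_phase(phases), np.arange(len(phases)) * 2.0, geometry
    )


class TestCoefficient:
    def test_default_value(self):
        g = td.AcquisitionGeometry.preset("gated-13")
        c = phase_to_temperature_coefficient(PRFModel(), g)
        assert c == pytest.approx(-0.0722, abs=2e-4)

    def test_te_zero_degenerate(self):
        g = geometry(echo_time_s=0.0)
        assert phase_to_temperature_coefficient(PRFModel(), g) == 0.0
        series = make_series(np.zeros((2, 6, 20, 20)), g)
        with pytest.raises(ConfigurationError):
            reconstruct_gated(series, [0])

    def test_linearity_in_te(self):
        c1 = phase_to_temperature_coefficient(PRFModel(), geometry(echo_time_s=0.018))
        c2 = phase_to_temperature_coefficient(PRFModel(), geometry(echo_time_s=0.036))
        assert c2 == pytest.approx(2 * c1)

    def test_zero_alpha_rejected(self):
        with pytest.raises(ConfigurationError):
            PRFModel(alpha_ppm_per_degc=0.0)


class TestGated:
    def test_zero_difference_identity(self):
        g = geometry()
        rng = np.random.default_rng(0)
        phi = rng.uniform(-3, 3, g.shape)
        series = make_series(np.broadcast_to(phi, (4,) + g.shape).copy(), g)
        temps = reconstruct_gated(series, [0])
        assert np.allclose(temps.temperature, 37.0, atol=1e-12)
        assert temps.valid.all()

    def test_plateau_recovered_exactly(self):
        g = geometry()
        c = phase_to_temperature_coefficient(PRFModel(), g)
        phi = np.zeros((3,) + g.shape)
        plateau = np.zeros(g.shape)
        plateau[2:4, 5:10, 5:10] = 30.0
        phi[1] = c * plateau
        phi[2] = c * plateau
        temps = reconstruct_gated(make_series(phi, g), [0])
        assert np.allclose(temps.temperature[2], 37.0 + plateau, atol=1e-9)

    def test_temporal_unwrapping_beats_naive_subtraction(self):
        """A ramp to +60 degC exceeds the single-step phase ambiguity;
        accumulating wrapped increments recovers it, direct wrapped
        subtraction is off by 2 pi / |c|."""
        g = geometry()
        c = phase_to_temperature_coefficient(PRFModel(), g)
        n = 61
        ramp = np.linspace(0.0, 60.0, n)
        phi = np.zeros((n,) + g.shape)
        phi[:, 3, 8, 8] = c * ramp
        temps = reconstruct_gated(make_series(phi, g), [0])
        assert temps.temperature[-1, 3, 8, 8] == pytest.approx(97.0, abs=1e-6)
        naive = wrap_phase(c * ramp[-1]) / c + 37.0
        assert abs(naive - 97.0) == pytest.approx(abs(2 * np.pi / c), abs=1e-6)

    def test_dead_voxels_invalid_not_nan(self):
        g = geometry()
        mag = np.ones((3,) + g.shape)
        mag[:, 0, 0, 0] = 0.0
        temps = reconstruct_gated(make_series(np.zeros((3,) + g.shape), g, mag), [0])
        assert not temps.valid[:, 0, 0, 0].any()
        assert np.isfinite(temps.temperature).all()
        assert np.all(temps.temperature[:, 0, 0, 0] == 37.0)

    def test_unwrap_guard_flags_jumps(self):
        g = geometry()
        phi = np.zeros((2,) + g.shape)
        phi[1, 1, 1, 1] = 0.99 * np.pi
        temps = reconstruct_gated(make_series(phi, g), [0])
        assert not temps.valid[1, 1, 1, 1]
        assert temps.valid[1, 2, 2, 2]

    def test_empty_baseline_rejected(self):
        g = geometry()
        series = make_series(np.zeros((2,) + g.shape), g)
        with pytest.raises(UsageError):
            reconstruct_gated(series, [])

    def test_linearity_in_phase(self):
        """Scaling all phase deviations by s scales reconstructed dT by s."""
        g = geometry()
        rng = np.random.default_rng(3)
        dev = 0.1 * rng.standard_normal((4,) + g.shape)
        dev[0] = 0.0
        t1 = reconstruct_gated(make_series(dev, g), [0])
        t2 = reconstruct_gated(make_series(3.0 * dev, g), [0])
        both = t1.valid & t2.valid
        np.testing.assert_allclose(
            (t2.temperature - 37.0)[both], 3.0 * (t1.temperature - 37.0)[both],
            atol=1e-9,
        )

    def test_noise_propagation(self):
        """At SNR 50, per-voxel temperature std ~ sqrt(2)/(snr |c|)."""
        g = geometry(n_slices=4, n_rows=12, n_cols=12)
        n = 200
        temp = np.full((n,) + g.shape, 37.0)
        truth = td.TemperatureSeries(temp, np.ones_like(temp, bool),
                                     np.arange(n) * 2.0, g)
        series, _ = td.synthesize_acquisition(truth, g, snr=50.0, seed=8,
                                              magnitude_texture=0.0)
        temps = reconstruct_gated(series, [0])
        c = phase_to_temperature_coefficient(PRFModel(), g)
        expected = np.sqrt(2.0) / (50.0 * abs(c))
        # ensemble over voxels, so each measurement carries independent
        # baseline and frame noise (hence the sqrt 2)
        stds = temps.temperature[1:].std(axis=(1, 2, 3))
        assert np.median(stds) == pytest.approx(expected, rel=0.15)


class TestBaselineLibrary:
    def test_identical_frames_zero_variance(self):
        g = geometry()
        rng = np.random.default_rng(1)
        phi = np.broadcast_to(rng.uniform(-2, 2, g.shape), (6,) + g.shape).copy()
        lib = build_baseline_library(make_series(phi, g), np.arange(6),
                                     register=False)
        assert lib.n_components == 0 or np.allclose(lib.explained_variance, 0.0)
        np.testing.assert_allclose(wrap_phase(lib.mean_phase - phi[0]), 0.0,
                                   atol=1e-12)

    def test_single_mode_dominates(self):
        """Library built as mean + a_f * pattern: first component explains
        > 99 % of the variance."""
        g = geometry()
        rng = np.random.default_rng(2)
        mean = rng.uniform(-1, 1, g.shape)
        pattern = rng.standard_normal(g.shape)
        pattern /= np.linalg.norm(pattern)
        a = 0.3 * np.sin(np.linspace(0, 4 * np.pi, 8))
        phi = mean[None] + a[:, None, None, None] * pattern[None]
        lib = build_baseline_library(make_series(phi, g), np.arange(8),
                                     n_components=3, register=False)
        assert lib.explained_variance_ratio[0] > 0.99

    def test_projection_completeness(self):
        """Residual of library frames on the full basis is numerically zero."""
        g = geometry()
        rng = np.random.default_rng(4)
        phi = 0.3 * rng.standard_normal((6,) + g.shape)
        series = make_series(phi, g)
        lib = build_baseline_library(series, np.arange(6), n_components=5,
                                     register=False)
        for f in range(6):
            dev = wrap_phase(phi[f] - lib.mean_phase)[lib.valid]
            coef = np.array([c[lib.valid] @ dev for c in lib.components])
            resid = dev - coef @ np.array(
                [c[lib.valid] for c in lib.components]
            )
            assert np.abs(resid).max() < 1e-9

    def test_too_few_frames_for_components_warns(self):
        g = geometry()
        phi = 0.1 * np.random.default_rng(5).standard_normal((5,) + g.shape)
        with pytest.warns(UserWarning, match="truncating"):
            lib = build_baseline_library(make_series(phi, g), np.arange(5),
                                         n_components=10, register=False)
        assert lib.n_components <= 4

    def test_minimum_library_size(self):
        g = geometry()
        phi = np.zeros((4,) + g.shape)
        with pytest.raises(UsageError):
            build_baseline_library(make_series(phi, g), np.arange(4))


class TestFreeBreathing:
    def test_null_case_recovers_baseline(self):
        """No motion, no drift, no heating: the fit absorbs everything and
        T = T0 with zero residual."""
        g = geometry()
        n = 8
        temp = np.full((n,) + g.shape, 37.0)
        truth = td.TemperatureSeries(temp, np.ones_like(temp, bool),
                                     np.arange(n) * 2.0, g)
        series, _ = td.synthesize_acquisition(truth, g, mode="gated", seed=6)
        lib = build_baseline_library(series, np.arange(6))
        bg = default_background_mask(g, (3, 10, 10), radius_mm=12.0)
        temps = reconstruct_free_breathing(series, lib, bg)
        assert np.allclose(temps.temperature[temps.valid], 37.0, atol=1e-6)

    def test_motion_correction_beats_uncorrected(self, free_breathing_case):
        """On a moving phantom with in-span drift, PCA correction recovers
        the hotspot while plain baseline subtraction fails."""
        case = free_breathing_case
        g, tip = case["geometry"], case["tip"]
        series, applied = case["synthesize"](seed=0)
        lib = build_baseline_library(series, np.arange(case["n_lib"]))
        bg = default_background_mask(g, tip, 25.0)
        rec = reconstruct_free_breathing(series, lib, bg)
        unc = reconstruct_gated(series, np.arange(case["n_lib"]))
        truth = case["truth"].temperature[-1]
        hot = case["hot_region"]
        m = rec.valid[-1] & hot
        rms = np.sqrt(np.mean((rec.temperature[-1][m] - truth[m]) ** 2))
        mu = unc.valid[-1] & hot
        rms_unc = np.sqrt(np.mean((unc.temperature[-1][mu] - truth[mu]) ** 2))
        assert rms < 1.0
        assert rms_unc > 5.0

    def test_singular_fit_recorded_not_raised(self):
        g = geometry()
        n = 8
        temp = np.full((n,) + g.shape, 37.0)
        truth = td.TemperatureSeries(temp, np.ones_like(temp, bool),
                                     np.arange(n) * 2.0, g)
        series, _ = td.synthesize_acquisition(truth, g, mode="gated", seed=6)
        lib = build_baseline_library(series, np.arange(6))
        empty_bg = np.zeros(g.shape, dtype=bool)
        temps = reconstruct_free_breathing(series, lib, empty_bg)
        assert not temps.valid.any()
        assert np.isfinite(temps.temperature).all()


class TestGating:
    def test_permissive_window_keeps_all(self):
        g = geometry()
        n = 10
        series = make_series(np.zeros((n,) + g.shape), g)
        trace = td.RespiratoryTrace.sinusoid(n, 2.0, amplitude_mm=10.0)
        gated, gtrace = td.gate_frames(series, trace, window_mm=10.0)
        assert gated.n_frames == n
        assert gtrace.n_frames == n

    def test_sinusoid_occupancy_matches_arcsine_law(self):
        """Kept fraction for a window of 10 % amplitude matches the time a
        sinusoid spends within that displacement band."""
        g = geometry(n_slices=1, n_rows=2, n_cols=2)
        n = 5000
        series = make_series(np.zeros((n,) + g.shape), g)
        trace = td.RespiratoryTrace.sinusoid(n, 0.013, period_s=4.1,
                                             amplitude_mm=20.0)
        gated, _ = td.gate_frames(series, trace, window_mm=2.0)
        expected = np.arccos(1.0 - 2.0 * 0.1) / np.pi
        assert gated.n_frames / n == pytest.approx(expected, rel=0.05)

    def test_empty_window_reports_minimum(self):
        g = geometry(n_slices=1, n_rows=2, n_cols=2)
        n = 20
        series = make_series(np.zeros((n,) + g.shape), g)
        trace = td.RespiratoryTrace.sinusoid(n, 2.0, period_s=4.3,
                                             amplitude_mm=20.0, phase0=0.5)
        with pytest.raises(UsageError, match="minimum achievable window"):
            td.gate_frames(series, trace, window_mm=0.0)

    def test_roundtrip_through_gating(self, phantom, gated_series):
        """Gating a static acquisition then reconstructing reproduces the
        truth to < 1e-6 degC on valid voxels."""
        trace = td.RespiratoryTrace.constant(gated_series.n_frames)
        gated, _ = td.gate_frames(gated_series, trace, window_mm=1.0)
        temps = reconstruct_gated(gated, np.arange(30))
        truth = phantom.temperature_series.temperature
        err = np.abs(temps.temperature - truth)[temps.valid]
        assert err.max() < 1e-6
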