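"""Bioheat solver, MR signal synthesis and cohort generator."""

import numpy as np
import pytest

import thermodose as td
from thermodose.errors import ConfigurationError, DomainError
from thermodose.synthetic import (
    generative_correlation,
    generative_log_correlation,
    noise_cv_for_correlation,
)
from thermodose.thermometry import PRFModel, phase_to_temperature_coefficient


def small_geometry(**kw):
    base = dict(n_slices=9, n_rows=24, n_cols=24)
    base.update(kw)
    return td.AcquisitionGeometry(**base)


class TestBioheat:
    def test_no_forcing_identity(self):
        """Zero source power on a uniform body-temperature field stays 37 degC."""
        g = small_geometry()
        temps = td.simulate_bioheat(g, td.TissueModel(), duration_s=20.0)
        assert np.all(temps.temperature == 37.0)

    def test_perfusion_only_exponential_decay(self):
        """With k = 0 and no source, T relaxes to T_body as exp(-w t / rho c)."""
        g = small_geometry()
        tissue = td.TissueModel(conductivity_w_per_m_degc=0.0)
        temps = td.simulate_bioheat(
            g, tissue, duration_s=60.0, time_step_s=0.25,
            initial_temperature=50.0, dirichlet=False,
        )
        rc = tissue.density_kg_per_m3 * tissue.heat_capacity_j_per_kg_degc
        lam = tissue.perfusion_w_per_m3_degc / rc
        expected = 37.0 + 13.0 * np.exp(-lam * 60.0)
        got = temps.temperature[-1]
        assert np.all(np.abs(got - expected) / (expected - 37.0) < 1e-3)

    def test_point_source_matches_heat_kernel(self):
        """An initial point excess spreads as the free-space Gaussian kernel."""
        g = td.AcquisitionGeometry(41, 41, 41, voxel_size_mm=(1.0, 1.0, 1.0))
        tissue = td.TissueModel(conductivity_w_per_m_degc=5.0,
                                perfusion_w_per_m3_degc=0.0)
        rc = tissue.density_kg_per_m3 * tissue.heat_capacity_j_per_kg_degc
        alpha = tissue.conductivity_w_per_m_degc / rc
        amp = 1e4
        init = np.full(g.shape, 37.0)
        init[20, 20, 20] += amp
        temps = td.simulate_bioheat(g, tissue, duration_s=10.0, time_step_s=0.1,
                                    initial_temperature=init)
        t_obs = 10.0
        coords = (np.arange(41) - 20) * 1e-3
        zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
        r2 = zz**2 + yy**2 + xx**2
        h3 = (1e-3) ** 3
        kernel = amp * h3 / (4 * np.pi * alpha * t_obs) ** 1.5 * np.exp(
            -r2 / (4 * alpha * t_obs)
        )
        sigma = np.sqrt(2 * alpha * t_obs)
        interior = r2 < (2.5 * sigma) ** 2
        got = temps.temperature[-1] - 37.0
        rms = np.sqrt(np.mean((got[interior] - kernel[interior]) ** 2))
        assert rms / kernel.max() < 0.02

    def test_unstable_step_names_bound(self):
        g = small_geometry()
        with pytest.raises(ConfigurationError, match="maximal stable step"):
            td.simulate_bioheat(g, td.TissueModel(), duration_s=10.0, time_step_s=50.0)

    def test_source_outside_grid_rejected(self):
        g = small_geometry()
        src = td.HeatSource(tip_voxel=(100, 5, 5), t_on_s=0.0, t_off_s=5.0)
        tissue = td.TissueModel(source=src)
        with pytest.raises(DomainError):
            td.simulate_bioheat(g, tissue, duration_s=10.0)

    def test_energy_decay_monotone(self):
        """Source off + Dirichlet boundary: max |T - T_body| never grows."""
        g = small_geometry()
        rng = np.random.default_rng(0)
        init = 37.0 + 5.0 * rng.random(g.shape)
        temps = td.simulate_bioheat(g, td.TissueModel(), duration_s=30.0,
                                    initial_temperature=init)
        excess = np.abs(temps.temperature - 37.0).max(axis=(1, 2, 3))
        assert np.all(np.diff(excess) <= 1e-12)

    def test_downsampling_consistency(self):
        """Doubling spatial resolution and block-averaging changes interior
        frame temperatures by < 0.2 degC RMS."""
        coarse = td.AcquisitionGeometry(12, 24, 24)
        fine = td.AcquisitionGeometry(
            24, 48, 48, voxel_size_mm=(1.5, 1.4, 1.4)
        )
        def run(g, tip):
            src = td.HeatSource(tip_voxel=tip, sigma_mm=9.0,
                                power_density_w_per_m3=1.4e6,
                                t_on_s=0.0, t_off_s=60.0)
            return td.simulate_bioheat(g, td.TissueModel(source=src), 60.0,
                                       time_step_s=0.2)
        tc = run(coarse, (6, 12, 12))
        tf = run(fine, (12, 24, 24))
        # full-weighting restriction (0.25, 0.5, 0.25 per axis) keeps the
        # averaged fine samples centered on the coarse voxel positions
        from scipy.ndimage import convolve1d

        restricted = tf.temperature
        for ax in (1, 2, 3):
            restricted = convolve1d(restricted, [0.25, 0.5, 0.25], axis=ax,
                                    mode="nearest")
        avg = restricted[:, ::2, ::2, ::2]
        inner = (slice(None), slice(2, -2), slice(2, -2), slice(2, -2))
        diff = avg[inner] - tc.temperature[inner]
        assert np.sqrt((diff**2).mean()) < 0.2


class TestAcquisition:
    def test_zero_delta_t_identity(self, gated_geometry):
        """Unheated object, no motion/noise/drift: phase is the static
        anatomical phase in every frame."""
        g = small_geometry()
        n = 5
        temp = np.full((n,) + g.shape, 37.0)
        truth = td.TemperatureSeries(temp, np.ones_like(temp, bool),
                                     np.arange(n) * 2.0, g)
        series, _ = td.synthesize_acquisition(truth, g, seed=0)
        for f in range(1, n):
            np.testing.assert_array_equal(series.phase[f], series.phase[0])
            np.testing.assert_array_equal(series.magnitude[f], series.magnitude[0])

    def test_single_voxel_prf_shift(self):
        """+10 degC at one voxel shifts its phase by c*10 ~ -0.722 rad."""
        g = small_geometry()
        temp = np.full((2,) + g.shape, 37.0)
        temp[1, 4, 10, 10] += 10.0
        truth = td.TemperatureSeries(temp, np.ones_like(temp, bool),
                                     np.array([0.0, 2.0]), g)
        series, _ = td.synthesize_acquisition(truth, g, seed=0)
        dphi = np.angle(np.exp(1j * (series.phase[1] - series.phase[0])))
        c = phase_to_temperature_coefficient(PRFModel(), g)
        assert dphi[4, 10, 10] == pytest.approx(10.0 * c, abs=1e-9)
        assert dphi[4, 10, 11] == pytest.approx(0.0, abs=1e-12)
        assert c == pytest.approx(-0.0722, abs=2e-4)

    def test_phase_noise_std_matches_snr(self):
        """At SNR 50, per-voxel phase std over Monte-Carlo frames ~ 1/snr."""
        g = small_geometry(n_slices=4, n_rows=12, n_cols=12)
        n = 200
        temp = np.full((n,) + g.shape, 37.0)
        truth = td.TemperatureSeries(temp, np.ones_like(temp, bool),
                                     np.arange(n) * 2.0, g)
        series, _ = td.synthesize_acquisition(
            truth, g, snr=50.0, seed=5, magnitude_texture=0.0
        )
        dev = np.angle(np.exp(1j * (series.phase - series.phase.mean(axis=0))))
        stds = dev.std(axis=0)
        assert np.median(stds) == pytest.approx(1.0 / 50.0, rel=0.10)

    def test_needle_void_and_domain_error(self):
        g = small_geometry()
        n = 2
        temp = np.full((n,) + g.shape, 37.0)
        truth = td.TemperatureSeries(temp, np.ones_like(temp, bool),
                                     np.arange(n) * 2.0, g)
        needle = td.NeedleSpec(tip_voxel=(4, 12, 12))
        series, _ = td.synthesize_acquisition(truth, g, needle=needle, seed=0)
        assert np.all(series.magnitude[:, needle.mask(g)] == 0.0)
        with pytest.raises(DomainError):
            td.NeedleSpec(tip_voxel=(4, 12, 400)).mask(g)

    def test_bitwise_reproducible(self):
        g = small_geometry()
        temp = np.full((3,) + g.shape, 37.0)
        truth = td.TemperatureSeries(temp, np.ones_like(temp, bool),
                                     np.arange(3) * 2.0, g)
        a, _ = td.synthesize_acquisition(truth, g, snr=20.0, seed=42,
                                         mode="free_breathing")
        b, _ = td.synthesize_acquisition(truth, g, snr=20.0, seed=42,
                                         mode="free_breathing")
        np.testing.assert_array_equal(a.magnitude, b.magnitude)
        np.testing.assert_array_equal(a.phase, b.phase)


class TestDay1Observation:
    def test_identity_and_scaling(self):
        assert td.make_day1_observation(16000.0, 0.0, 0.0) == 16000.0
        assert td.make_day1_observation(10000.0, 0.10, 0.0) == pytest.approx(11000.0)

    def test_noise_cv_calibrated(self):
        """Sample CV over 10,000 draws matches the requested noise CV."""
        rng = np.random.default_rng(7)
        draws = np.array([
            td.make_day1_observation(10000.0, 0.0, 0.15, rng) for _ in range(10000)
        ])
        cv = draws.std() / draws.mean()
        assert cv == pytest.approx(0.15, rel=0.10)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(DomainError):
            td.make_day1_observation(0.0)


class TestCohort:
    def test_noiseless_pairs_correlate_perfectly(self):
        _, cohort = td.generate_cohort(27, noise_cv=0.0, p_excluded=0.0, seed=1)
        x = cohort.data["predicted_volume_mm3"]
        y = cohort.data["ablation_volume_mm3"]
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_same_seed_bitwise_identical(self):
        _, a = td.generate_cohort(27, seed=9)
        _, b = td.generate_cohort(27, seed=9)
        assert a.data.equals(b.data)

    def test_mean_estimated_r_matches_generative(self):
        """At generative r = 0.9, the mean sample r over 500 replicate
        cohorts of n = 27 is within 0.03 of 0.9."""
        cv = noise_cv_for_correlation(0.9, 0.33)
        rng_seed = 1000
        rs = []
        for k in range(500):
            _, cohort = td.generate_cohort(
                27, sigma_log=0.33, noise_cv=cv, p_excluded=0.0,
                seed=rng_seed + k, build_phantoms=False,
            )
            x = cohort.data["predicted_volume_mm3"].to_numpy()
            y = cohort.data["ablation_volume_mm3"].to_numpy()
            rs.append(np.corrcoef(x, y)[0, 1])
        assert np.mean(rs) == pytest.approx(0.9, abs=0.03)

    def test_generative_correlation_closed_forms(self):
        cv = noise_cv_for_correlation(0.9, 0.33)
        assert generative_correlation(0.33, cv) == pytest.approx(0.9, abs=1e-9)
        assert generative_log_correlation(0.33, cv) > 0.9

    def test_phantom_truth_consistency(self):
        cases, cohort = td.generate_cohort(5, p_excluded=0.0, seed=3)
        for case, (_, row) in zip(cases, cohort.data.iterrows()):
            assert case.lethal_volume_mm3 == pytest.approx(
                row["predicted_volume_mm3"]
            )
            # lethal mask is exactly the thresholded synthetic dose field
            assert np.array_equal(
                case.lethal, case.cem43 >= case.dose_params.lethal_threshold_min
            )
            assert case.needle.any()
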