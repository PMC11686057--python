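"""Shared fixtures: physics phantom, gated acquisition, free-breathing cases."""

import numpy as np
import pytest

import thermodose as td


@pytest.fixture(scope="session")
def gated_geometry():
    return td.AcquisitionGeometry.preset("gated-13")


@pytest.fixture(scope="session")
def phantom(gated_geometry):
    """Default full-physics heated phantom (180 s emission)."""
    return td.make_phantom(gated_geometry)


@pytest.fixture(scope="session")
def gated_series(phantom, gated_geometry):
    """Noiseless gated acquisition of the default phantom, with needle void."""
    series, _ = td.synthesize_acquisition(
        phantom.temperature_series, gated_geometry,
        needle=td.NeedleSpec(phantom.tip_voxel), mode="gated", seed=11,
    )
    return series


@pytest.fixture(scope="session")
def free_breathing_case():
    """Factory for a free-breathing phantom with an analytic hotspot.

    Returns a dict with the truth series, geometry, tip, the hotspot
    region mask, and frame bookkeeping; ``synthesize`` produces the
    acquisition for a given seed/SNR with motion and in-span drift.
    """
    g = td.AcquisitionGeometry.preset("free-20", matrix=48)
    n_lib, n_heat = 24, 16
    n = n_lib + n_heat
    tip = (10, 24, 24)
    grids = np.meshgrid(
        *[np.arange(s) * v for s, v in zip(g.shape, g.voxel_size_mm)], indexing="ij"
    )
    tip_mm = [i * v for i, v in zip(tip, g.voxel_size_mm)]
    r2 = sum((a - b) ** 2 for a, b in zip(grids, tip_mm))
    hot = np.exp(-r2 / (2 * 8.0**2))
    temp = np.full((n,) + g.shape, 37.0)
    for f in range(n_lib, n):
        temp[f] += 25.0 * ((f - n_lib + 1) / n_heat) * hot
    truth = td.TemperatureSeries(temp, np.ones_like(temp, bool), np.arange(n) * 2.0, g)

    def synthesize(seed, snr=None):
        trace = td.RespiratoryTrace.sinusoid(
            n, 2.0, period_s=5.0, amplitude_mm=15.0, phase0=0.7 * seed
        )
        return td.synthesize_acquisition(
            truth, g, snr=snr, drift=(0.01, 0.02, 0.015), trace=trace,
            mode="free_breathing", seed=seed,
        )

    return {
        "geometry": g, "truth": truth, "tip": tip, "n_lib": n_lib,
        "hot_region": r2 <= 20.0**2, "synthesize": synthesize,
    }
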