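"""PRF-shift temperature reconstruction.

The water proton resonance frequency decreases approximately linearly
with temperature (alpha ~ -0.01 ppm/degC), so a temperature change DT
shifts the phase of a gradient-echo acquisition by

    dphi = 2 pi gamma_bar B0 TE alpha DT = c DT        [rad]

with c ~ -0.0722 rad/degC at 1.5 T and TE = 18 ms.  Two reconstruction
modes are provided:

* ``reconstruct_gated`` - single-baseline subtraction for
  respiratory-gated acquisitions, with temporal phase unwrapping so the
  accumulated heating may exceed the single-step pi/|c| ambiguity.
* ``reconstruct_free_breathing`` - multi-baseline correction for
  free-breathing acquisitions: integer-voxel translation registration of
  each frame to a pre-heating reference followed by a least-squares fit
  of the background phase on a PCA basis of pre-heating phase
  variations; the fit residual is converted to temperature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import match_template

from .containers import ComplexVolumeSeries, RespiratoryTrace, TemperatureSeries, wrap_phase
from .errors import ConfigurationError, UsageError
from .geometry import AcquisitionGeometry

logger = logging.getLogger(__name__)

#: fraction of the median baseline magnitude below which a voxel is
#: treated as signal-free (needle void, outside the body)
DEFAULT_SIGNAL_FLOOR_FRACTION = 0.1

#: |wrapped per-frame increment| above this multiple of pi is treated as
#: an unwrapping failure and the voxel flagged invalid from then on
UNWRAP_GUARD = 0.95


@dataclass(frozen=True)
class PRFModel:
    """PRF thermal coefficient and baseline temperature assumption."""

    alpha_ppm_per_degc: float = -0.01
    gamma_bar_mhz_per_t: float = 42.577
    baseline_temperature_degc: float = 37.0

    def __post_init__(self) -> None:
        if self.alpha_ppm_per_degc >= 0:
            raise ConfigurationError("PRF coefficient alpha must be negative")


def phase_to_temperature_coefficient(
    prf: PRFModel, geometry: AcquisitionGeometry
) -> float:
    """Phase change per degree Celsius, in rad/degC.

    c = 2 pi * (gamma_bar MHz/T -> Hz/T) * (alpha ppm -> fraction) * B0 * TE.
    Negative at clinical field strengths; zero only in the degenerate
    TE = 0 limit (in which temperature is unobservable and the
    reconstructions refuse to run).
    """
    if prf.alpha_ppm_per_degc == 0:
        raise ConfigurationError("alpha = 0 makes temperature unobservable")
    return (
        2.0 * np.pi
        * prf.gamma_bar_mhz_per_t * 1e6
        * prf.alpha_ppm_per_degc * 1e-6
        * geometry.field_strength_t
        * geometry.echo_time_s
    )


def _signal_floor(baseline_magnitude: np.ndarray, fraction: float) -> float:
    med = float(np.median(baseline_magnitude[baseline_magnitude > 0])) if np.any(
        baseline_magnitude > 0
    ) else 0.0
    return fraction * med


def reconstruct_gated(
    series: ComplexVolumeSeries,
    baseline_frames,
    prf: PRFModel | None = None,
    signal_floor_fraction: float = DEFAULT_SIGNAL_FLOOR_FRACTION,
) -> TemperatureSeries:
    """Single-baseline PRF reconstruction for gated acquisitions.

    The baseline phase is the complex average of the pre-ablation gated
    frames.  Per-frame phase increments are wrapped to (-pi, pi] and
    accumulated (temporal unwrapping), so the total temperature rise may
    exceed the single-step ambiguity of pi/|c| (~43 degC at defaults) as
    long as no single 2 s step jumps by more than ~half of that.
    Voxels whose magnitude falls below the signal floor, or whose phase
    increment exceeds the unwrapping guard, are marked invalid; their
    temperature is reported as the baseline temperature, never NaN.
    """
    prf = prf or PRFModel()
    baseline_frames = np.atleast_1d(np.asarray(baseline_frames, dtype=int))
    if baseline_frames.size == 0:
        raise UsageError("baseline frame set must not be empty")
    c = phase_to_temperature_coefficient(prf, series.geometry)
    if c == 0:
        raise ConfigurationError("phase-temperature coefficient is zero (TE = 0?)")

    z = series.complex_data()
    baseline = z[baseline_frames].mean(axis=0)
    baseline_phase = np.angle(baseline)
    floor = _signal_floor(np.abs(baseline), signal_floor_fraction)

    n = series.n_frames
    temp = np.empty_like(series.magnitude)
    valid = series.magnitude > floor
    # voxels dead in the baseline stay invalid everywhere
    valid &= (np.abs(baseline) > floor)[None]

    cum = np.zeros(series.geometry.shape)
    prev_phase = baseline_phase
    broken = np.zeros(series.geometry.shape, dtype=bool)
    for f in range(n):
        inc = wrap_phase(series.phase[f] - prev_phase)
        broken |= np.abs(inc) > UNWRAP_GUARD * np.pi
        cum = cum + inc
        temp[f] = prf.baseline_temperature_degc + cum / c
        valid[f] &= ~broken
        prev_phase = series.phase[f]
    temp[~valid] = prf.baseline_temperature_degc
    return TemperatureSeries(temp, valid, series.timestamps, series.geometry)


# ---------------------------------------------------------------------------
# Multi-baseline PCA library and free-breathing reconstruction
# ---------------------------------------------------------------------------

@dataclass
class BaselineLibrary:
    """Mean pre-heating phase plus principal components of its variations.

    Components are orthonormal over the library's valid-voxel support and
    ordered by nonincreasing explained variance.  ``reference_magnitude``
    is the registration target for subsequent frames.
    """

    mean_phase: np.ndarray
    components: np.ndarray            # (k, slice, row, col)
    explained_variance: np.ndarray    # per component, nonincreasing
    valid: np.ndarray                 # voxels usable for fitting
    reference_magnitude: np.ndarray
    signal_floor: float

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        tot = self.explained_variance.sum()
        if tot == 0:
            return np.zeros_like(self.explained_variance)
        return self.explained_variance / tot


def _integer_shift(arr: np.ndarray, shift: tuple[int, ...]) -> np.ndarray:
    """Translate by whole voxels with edge replication."""
    out = arr
    for ax, s in enumerate(shift):
        s = int(s)
        if s == 0:
            continue
        out = np.roll(out, s, axis=ax)
        sl = [slice(None)] * out.ndim
        if s > 0:
            sl[ax] = slice(0, s)
            edge = [slice(None)] * out.ndim
            edge[ax] = slice(s, s + 1)
        else:
            sl[ax] = slice(out.shape[ax] + s, out.shape[ax])
            edge = [slice(None)] * out.ndim
            edge[ax] = slice(out.shape[ax] + s - 1, out.shape[ax] + s)
        out = out.copy()
        out[tuple(sl)] = out[tuple(edge)]
    return out


def _edge_margin_mask(shape: tuple[int, ...], shift: tuple[int, ...]) -> np.ndarray:
    """True where translated data is genuine (not edge-replicated)."""
    ok = np.ones(shape, dtype=bool)
    for ax, s in enumerate(shift):
        s = int(s)
        if s == 0:
            continue
        sl = [slice(None)] * len(shape)
        sl[ax] = slice(0, s) if s > 0 else slice(shape[ax] + s, shape[ax])
        ok[tuple(sl)] = False
    return ok


def _register_to(ref_mag: np.ndarray, mag: np.ndarray) -> tuple[int, ...]:
    """Integer-voxel shift aligning ``mag`` to ``ref_mag``.

    Normalized cross-correlation of the reference's interior against the
    moving volume (template matching): the cropped template is immune to
    the edge bands that breathing translation slides in and out of the
    field of view, and every candidate shift is scored on the full
    template, so the estimate carries no bias toward small shifts.  The
    search range is a quarter of each dimension.

    Rigid translation survives projection, so the 3D shift is assembled
    from 2D estimates, which keeps per-frame registration cheap on long
    series: the through-slice mean projection gives the (row, col)
    shift; that shift is undone and the through-row projection of the
    compensated volume gives the slice shift (projecting along an
    uncompensated motion axis is not shift invariant at the edges).
    """

    def ncc_shift_2d(ref2d: np.ndarray, mov2d: np.ndarray) -> tuple[int, int]:
        margin = [max(1, n // 4) for n in ref2d.shape]
        template = ref2d[tuple(slice(m, -m) for m in margin)]
        score = match_template(mov2d, template, pad_input=False)
        idx = np.unravel_index(np.argmax(score), score.shape)
        return tuple(int(m - i) for i, m in zip(idx, margin))

    row_col = ncc_shift_2d(ref_mag.mean(axis=0), mag.mean(axis=0))
    compensated = _integer_shift(mag, (0, row_col[0], row_col[1]))
    slice_col = ncc_shift_2d(ref_mag.mean(axis=1), compensated.mean(axis=1))
    return (slice_col[0], row_col[0], row_col[1])


def build_baseline_library(
    series: ComplexVolumeSeries,
    library_frames,
    n_components: int | None = None,
    variance_fraction: float = 0.95,
    max_components: int = 8,
    signal_floor_fraction: float = DEFAULT_SIGNAL_FLOOR_FRACTION,
    register: bool = True,
) -> BaselineLibrary:
    """Learn the background-phase model from pre-heating frames.

    Frames should span at least one full respiratory cycle so the
    motion-induced phase patterns are represented.  Each library frame is
    registered (integer-voxel translation of its magnitude) to the first
    library frame, its phase deviation from the circular mean is
    temporally unwrapped, and a PCA of the deviations is taken over the
    voxels valid in every library frame.  The default component count is
    the smallest number explaining ``variance_fraction`` of the library
    variance, capped at ``max_components``.
    """
    library_frames = np.atleast_1d(np.asarray(library_frames, dtype=int))
    if library_frames.size < 5:
        raise UsageError(
            "baseline library needs >= 5 frames spanning the respiratory cycle"
        )
    sub = series.subset(library_frames)
    floor = _signal_floor(sub.magnitude[0], signal_floor_fraction)
    ref_mag = sub.magnitude[0]

    mags = np.empty_like(sub.magnitude)
    phases = np.empty_like(sub.phase)
    valid = np.ones(series.geometry.shape, dtype=bool)
    for f in range(sub.n_frames):
        shift = _register_to(ref_mag, sub.magnitude[f]) if register else (0, 0, 0)
        mags[f] = _integer_shift(sub.magnitude[f], shift)
        phases[f] = _integer_shift(sub.phase[f], shift)
        valid &= _edge_margin_mask(series.geometry.shape, shift)
        valid &= mags[f] > floor

    mean_phase = np.angle(np.exp(1j * phases).mean(axis=0))
    dev = wrap_phase(phases - mean_phase[None])
    # re-center so deviations are arithmetically zero-mean
    mean_phase = wrap_phase(mean_phase + dev.mean(axis=0))
    dev = wrap_phase(phases - mean_phase[None])

    d = dev.reshape(sub.n_frames, -1)[:, valid.ravel()]
    d = d - d.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    var = s**2 / max(sub.n_frames - 1, 1)

    k_max = min(sub.n_frames - 1, max_components, vt.shape[0])
    if n_components is not None:
        if n_components > k_max:
            msg = (
                f"requested {n_components} components but only {k_max} available; "
                "truncating"
            )
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
        k = min(n_components, k_max)
    else:
        tot = var.sum()
        if tot == 0:
            k = 0
        else:
            cum = np.cumsum(var) / tot
            k = int(np.searchsorted(cum, variance_fraction) + 1)
            k = min(k, k_max)
    comps = np.zeros((k,) + series.geometry.shape)
    for i in range(k):
        comp = np.zeros(series.geometry.shape)
        comp[valid] = vt[i]
        comps[i] = comp
    return BaselineLibrary(
        mean_phase=mean_phase,
        components=comps,
        explained_variance=var[:k] if k else var[:0],
        valid=valid,
        reference_magnitude=ref_mag,
        signal_floor=floor,
    )


def default_background_mask(
    geometry: AcquisitionGeometry, tip_voxel, radius_mm: float = 25.0
) -> np.ndarray:
    """Voxels farther than ``radius_mm`` from the antenna tip.

    The heated neighbourhood around the tip must be excluded from the
    background fit or true heating would be absorbed into it.
    """
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(geometry.shape, geometry.voxel_size_mm)],
        indexing="ij",
    )
    tip_mm = [i * s for i, s in zip(tip_voxel, geometry.voxel_size_mm)]
    d2 = sum((g - t) ** 2 for g, t in zip(grids, tip_mm))
    return d2 > radius_mm**2


def reconstruct_free_breathing(
    series: ComplexVolumeSeries,
    library: BaselineLibrary,
    background_mask: np.ndarray,
    prf: PRFModel | None = None,
) -> TemperatureSeries:
    """Multi-baseline PCA-corrected reconstruction for free breathing.

    Per frame: (1) integer-voxel translation registration of the
    magnitude to the library reference, (2) least-squares fit of the
    registered phase deviation on {constant, components} over the
    background mask, (3) temperature from the fit residual.  Residual
    maps are temporally unwrapped across frames so heating beyond the
    single-step ambiguity is recovered.  Frames whose fit is singular
    (background mask too small) are recorded as fully invalid rather
    than raising.
    """
    prf = prf or PRFModel()
    c = phase_to_temperature_coefficient(prf, series.geometry)
    if c == 0:
        raise ConfigurationError("phase-temperature coefficient is zero (TE = 0?)")
    background_mask = np.asarray(background_mask, dtype=bool)

    n = series.n_frames
    temp = np.full_like(series.magnitude, prf.baseline_temperature_degc)
    valid = np.zeros(series.magnitude.shape, dtype=bool)
    k = library.n_components
    prev_resid: np.ndarray | None = None

    for f in range(n):
        shift = _register_to(library.reference_magnitude, series.magnitude[f])
        mag = _integer_shift(series.magnitude[f], shift)
        phase = _integer_shift(series.phase[f], shift)
        ok = (
            library.valid
            & _edge_margin_mask(series.geometry.shape, shift)
            & (mag > library.signal_floor)
        )
        fit_mask = ok & background_mask
        if fit_mask.sum() < k + 2:
            logger.warning("frame %d: background fit singular; frame marked invalid", f)
            prev_resid = None
            continue
        dev = wrap_phase(phase - library.mean_phase)
        cols = [np.ones(int(fit_mask.sum()))]
        cols += [comp[fit_mask] for comp in library.components]
        a = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(a, dev[fit_mask], rcond=None)
        model = np.full(series.geometry.shape, coef[0])
        for i in range(k):
            model += coef[1 + i] * library.components[i]
        resid = wrap_phase(dev - model)
        if prev_resid is not None:
            resid = prev_resid + wrap_phase(resid - prev_resid)
        prev_resid = resid
        temp[f] = prf.baseline_temperature_degc + resid / c
        temp[f][~ok] = prf.baseline_temperature_degc
        valid[f] = ok
    return TemperatureSeries(temp, valid, series.timestamps, series.geometry)


def gate_frames(
    series: ComplexVolumeSeries,
    trace: RespiratoryTrace,
    window_mm: float,
) -> tuple[ComplexVolumeSeries, RespiratoryTrace]:
    """Keep frames within ``window_mm`` of end-expiration.

    Emulates the thoracic-belt gating selection.  Timestamps of the kept
    frames are preserved, so the gated subseries is irregularly spaced
    and downstream dose accumulation uses the true frame intervals.
    """
    if trace.n_frames != series.n_frames:
        raise UsageError("respiratory trace must be aligned with the series frames")
    d = np.abs(trace.displacement_mm)
    keep = np.flatnonzero(d <= window_mm)
    if keep.size == 0:
        raise UsageError(
            f"no frame within {window_mm} mm of end-expiration; "
            f"minimum achievable window is {d.min():.3f} mm"
        )
    return series.subset(keep), trace.subset(keep)
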