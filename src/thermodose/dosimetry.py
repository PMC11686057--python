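"""CEM43 thermal-dose accumulation (Sapareto-Dewey model).

The cumulative equivalent minutes at 43 degC convert an arbitrary
time-temperature history into the exposure duration at the reference
temperature with the same biological effect:

    CEM43 = sum_frames dt[min] * R^(43 - T)

with R = 0.5 for T >= 43 degC and R = 0.25 below.  Tissue receiving
240 equivalent minutes or more is considered irreversibly coagulated;
thresholding the dose map at 240 min yields the thermometry-predicted
lesion mask.

Temperature is held piecewise-constant per frame (left-endpoint hold
over the inter-frame interval), matching a 2 s real-time stream; dose
keeps accumulating through the post-ablation cooling frames.  No
low-temperature cutoff is applied - sub-39 degC contributions are
negligible by construction of the R weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .containers import TemperatureSeries
from .errors import ConfigurationError, UsageError
from .geometry import AcquisitionGeometry

logger = logging.getLogger(__name__)

#: plausibility band for reconstructed tissue temperature, degC
SANITY_RANGE_DEGC = (0.0, 150.0)


@dataclass(frozen=True)
class DoseParams:
    """Sapareto model constants and the lethal-dose threshold."""

    reference_temperature_degc: float = 43.0
    r_above: float = 0.5
    r_below: float = 0.25
    lethal_threshold_min: float = 240.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r_below <= self.r_above < 1.0):
            raise ConfigurationError("require 0 < R_below <= R_above < 1")
        if self.lethal_threshold_min <= 0:
            raise ConfigurationError("lethal threshold must be positive")


@dataclass
class ThermalDoseMap:
    """Per-voxel CEM43 in equivalent minutes at 43 degC.

    ``coverage`` marks voxels with at least one valid frame; dose is
    zero outside coverage.  ``suspect`` marks voxels that at some frame
    carried a temperature outside the sanity range (still accumulated).
    """

    cem43: np.ndarray
    coverage: np.ndarray
    geometry: AcquisitionGeometry
    suspect: np.ndarray


class CEM43Accumulator:
    """Streaming CEM43 accumulation; identical to batch by construction."""

    def __init__(self, geometry: AcquisitionGeometry, params: DoseParams | None = None):
        self.geometry = geometry
        self.params = params or DoseParams()
        self.cem43 = np.zeros(geometry.shape)
        self.coverage = np.zeros(geometry.shape, dtype=bool)
        self.suspect = np.zeros(geometry.shape, dtype=bool)

    def add_frame(
        self, temperature: np.ndarray, dt_s: float, valid: np.ndarray | None = None
    ) -> None:
        t = np.asarray(temperature, dtype=float)
        v = np.ones(t.shape, dtype=bool) if valid is None else np.asarray(valid, bool)
        lo, hi = SANITY_RANGE_DEGC
        bad = v & ((t < lo) | (t > hi))
        if bad.any():
            logger.warning(
                "%d voxel(s) outside the %s-%s degC sanity range; still accumulated",
                int(bad.sum()), lo, hi,
            )
            self.suspect |= bad
        p = self.params
        r = np.where(t >= p.reference_temperature_degc, p.r_above, p.r_below)
        incr = (dt_s / 60.0) * r ** (p.reference_temperature_degc - t)
        self.cem43 += np.where(v, incr, 0.0)
        self.coverage |= v

    def result(self) -> ThermalDoseMap:
        cem = np.where(self.coverage, self.cem43, 0.0)
        return ThermalDoseMap(cem, self.coverage.copy(), self.geometry, self.suspect.copy())


def frame_hold_intervals(timestamps: np.ndarray, fallback_s: float) -> np.ndarray:
    """Hold duration per frame under the left-endpoint convention.

    Frame f is held until frame f+1 arrives; the last frame is held for
    the preceding interval (or ``fallback_s`` for a single frame).
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.size > 1 and np.any(np.diff(timestamps) <= 0):
        raise UsageError("frame timestamps must be strictly increasing")
    if timestamps.size == 1:
        return np.array([fallback_s])
    dts = np.diff(timestamps)
    return np.concatenate([dts, dts[-1:]])


def accumulate_cem43(
    temps: TemperatureSeries, params: DoseParams | None = None
) -> ThermalDoseMap:
    """Accumulate the CEM43 dose map over a whole temperature series."""
    acc = CEM43Accumulator(temps.geometry, params)
    dts = frame_hold_intervals(temps.timestamps, temps.geometry.frame_interval_s)
    for f in range(temps.n_frames):
        acc.add_frame(temps.temperature[f], dts[f], temps.valid[f])
    return acc.result()


def lethal_mask(dose: ThermalDoseMap, params: DoseParams | None = None) -> np.ndarray:
    """Voxels at or above the lethal threshold (inclusive), within coverage."""
    params = params or DoseParams()
    if not np.all(np.isfinite(dose.cem43)):
        raise UsageError("dose map contains non-finite values")
    return (dose.cem43 >= params.lethal_threshold_min) & dose.coverage
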