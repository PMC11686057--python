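"""In-memory containers shared by the synthesis and reconstruction stages.

``ComplexVolumeSeries`` holds the raw magnitude/phase EPI stream,
``TemperatureSeries`` the reconstructed (or ground-truth) temperature
maps with a per-frame validity mask, and ``RespiratoryTrace`` the
craniocaudal displacement recorded alongside the frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, UsageError
from .geometry import AcquisitionGeometry


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase to the principal interval (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi, dtype=float)))


@dataclass
class ComplexVolumeSeries:
    """Time-ordered magnitude + phase volumes, shape (frame, slice, row, col)."""

    magnitude: np.ndarray
    phase: np.ndarray
    timestamps: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ConfigurationError(
                f"magnitude shape {self.magnitude.shape} != phase shape {self.phase.shape}"
            )
        if self.magnitude.ndim != 4:
            raise ConfigurationError("series arrays must be 4D (frame, slice, row, col)")
        if self.magnitude.shape[1:] != self.geometry.shape:
            raise ConfigurationError(
                f"series spatial shape {self.magnitude.shape[1:]} does not match "
                f"geometry {self.geometry.shape}"
            )
        if len(self.timestamps) != self.n_frames:
            raise ConfigurationError("one timestamp per frame required")
        if self.n_frames > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ConfigurationError("timestamps must be strictly increasing")
        if np.any(self.magnitude < 0):
            raise ConfigurationError("magnitude must be nonnegative")
        if np.any(self.phase > np.pi) or np.any(self.phase <= -np.pi - 1e-12):
            raise ConfigurationError("phase must be wrapped to (-pi, pi]")

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    def complex_data(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * self.phase)

    def subset(self, frames) -> "ComplexVolumeSeries":
        frames = np.asarray(frames)
        return ComplexVolumeSeries(
            self.magnitude[frames], self.phase[frames],
            self.timestamps[frames], self.geometry,
        )


@dataclass
class TemperatureSeries:
    """Per-frame temperature maps in degrees Celsius with validity mask."""

    temperature: np.ndarray
    valid: np.ndarray
    timestamps: np.ndarray
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.temperature.ndim != 4:
            raise ConfigurationError("temperature must be 4D (frame, slice, row, col)")
        if self.valid.shape != self.temperature.shape:
            raise ConfigurationError("validity mask must match temperature shape")
        if len(self.timestamps) != self.temperature.shape[0]:
            raise ConfigurationError("one timestamp per frame required")

    @property
    def n_frames(self) -> int:
        return self.temperature.shape[0]

    def subset(self, frames) -> "TemperatureSeries":
        frames = np.asarray(frames)
        return TemperatureSeries(
            self.temperature[frames], self.valid[frames],
            self.timestamps[frames], self.geometry,
        )


@dataclass
class RespiratoryTrace:
    """Craniocaudal displacement per frame, in mm from end-expiration.

    Displacement is nonnegative by convention: 0 is the end-expiratory
    resting position the gating belt targets, ``amplitude_mm`` the peak
    excursion (the liver moves roughly 10-40 mm craniocaudally under
    free breathing).
    """

    displacement_mm: np.ndarray
    period_s: float
    amplitude_mm: float

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        if not (0.0 <= self.amplitude_mm <= 40.0):
            raise ConfigurationError("amplitude must lie within 0-40 mm")
        if np.any(self.displacement_mm < -1e-9) or np.any(
            self.displacement_mm > self.amplitude_mm + 1e-9
        ):
            raise ConfigurationError("displacement must be bounded by the amplitude")

    @property
    def n_frames(self) -> int:
        return len(self.displacement_mm)

    @classmethod
    def sinusoid(
        cls,
        n_frames: int,
        frame_interval_s: float = 2.0,
        period_s: float = 5.0,
        amplitude_mm: float = 15.0,
        phase0: float = 0.0,
    ) -> "RespiratoryTrace":
        """Sinusoidal breathing: d(t) = A (1 - cos(2 pi t / T + phase0)) / 2."""
        t = np.arange(n_frames) * frame_interval_s
        d = amplitude_mm * (1.0 - np.cos(2 * np.pi * t / period_s + phase0)) / 2.0
        return cls(d, period_s, amplitude_mm)

    @classmethod
    def constant(cls, n_frames: int, value_mm: float = 0.0) -> "RespiratoryTrace":
        return cls(
            np.full(n_frames, value_mm), period_s=np.inf,
            amplitude_mm=max(value_mm, 0.0),
        )

    def subset(self, frames) -> "RespiratoryTrace":
        return replace(self, displacement_mm=self.displacement_mm[np.asarray(frames)])
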