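"""NIfTI-1 I/O for volumes, series and masks, plus the YAML sidecar.

On-disk convention: single volumes are stored with data axes
(slice, row, col); 4D series move time to the fourth dimension.  The
affine is diagonal in the voxel spacings (mm) and the physical unit of
the stored quantity (degC, minutes, radians, ...) is recorded in the
header ``descrip`` field.  Arrays round-trip bitwise (float64 storage)
and the affine to 1e-6.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .containers import ComplexVolumeSeries, TemperatureSeries
from .dosimetry import ThermalDoseMap
from .errors import FormatError
from .geometry import AcquisitionGeometry
from .thermometry import PRFModel


def _affine(geometry: AcquisitionGeometry) -> np.ndarray:
    return np.diag(list(geometry.voxel_size_mm) + [1.0])


def _image(data: np.ndarray, geometry: AcquisitionGeometry, units: str) -> nib.Nifti1Image:
    img = nib.Nifti1Image(data, _affine(geometry))
    img.header["descrip"] = units.encode()[:79]
    if data.ndim == 4:
        img.header["pixdim"][4] = geometry.frame_interval_s
    return img


def write_volume(path, array3d: np.ndarray, geometry: AcquisitionGeometry,
                 units: str = "") -> None:
    arr = np.asarray(array3d)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(_image(arr, geometry, units), str(path))


def read_volume(path) -> tuple[np.ndarray, np.ndarray, str]:
    """Returns (array, voxel sizes mm, units string)."""
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    vox = np.abs(np.diag(img.affine)[:3])
    units = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="replace")
    return arr, vox, units


def write_series(path, array4d: np.ndarray, geometry: AcquisitionGeometry,
                 units: str = "") -> None:
    """4D series (frame, slice, row, col) stored with time as dim 4."""
    data = np.moveaxis(np.asarray(array4d, dtype=np.float64), 0, -1)
    nib.save(_image(data, geometry, units), str(path))


def read_series(path) -> tuple[np.ndarray, np.ndarray, str]:
    arr, vox, units = read_volume(path)
    if arr.ndim != 4:
        raise FormatError(f"{path}: expected a 4D series, got shape {arr.shape}")
    return np.moveaxis(arr, -1, 0), vox, units


def write_sidecar(path, geometry: AcquisitionGeometry, timestamps,
                  prf: PRFModel | None = None, seed: int | None = None,
                  extra: dict | None = None) -> None:
    doc = {
        "geometry": asdict(geometry),
        "timestamps_s": [float(t) for t in timestamps],
        "prf": asdict(prf) if prf is not None else None,
        "seed": seed,
    }
    doc.update(extra or {})
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_sidecar(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    g = doc["geometry"]
    g["voxel_size_mm"] = tuple(g["voxel_size_mm"])
    doc["geometry"] = AcquisitionGeometry(**g)
    if doc.get("prf"):
        doc["prf"] = PRFModel(**doc["prf"])
    return doc


def write_complex_series(out_dir, series: ComplexVolumeSeries, prefix: str = "thermo",
                         prf: PRFModel | None = None, seed: int | None = None) -> dict:
    """Magnitude + phase NIfTI pair plus a YAML sidecar; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "magnitude": out_dir / f"{prefix}_magnitude.nii",
        "phase": out_dir / f"{prefix}_phase.nii",
        "sidecar": out_dir / f"{prefix}_sidecar.yaml",
    }
    write_series(paths["magnitude"], series.magnitude, series.geometry, "a.u.")
    write_series(paths["phase"], series.phase, series.geometry, "radians")
    write_sidecar(paths["sidecar"], series.geometry, series.timestamps, prf, seed)
    return paths


def read_complex_series(out_dir, prefix: str = "thermo") -> ComplexVolumeSeries:
    out_dir = Path(out_dir)
    mag, vox_m, _ = read_series(out_dir / f"{prefix}_magnitude.nii")
    phase, vox_p, _ = read_series(out_dir / f"{prefix}_phase.nii")
    if mag.shape != phase.shape:
        raise FormatError(
            f"magnitude shape {mag.shape} does not match phase shape {phase.shape}"
        )
    if not np.allclose(vox_m, vox_p, atol=1e-6):
        raise FormatError(
            f"voxel sizes differ between magnitude {tuple(vox_m)} and "
            f"phase {tuple(vox_p)}"
        )
    if np.any(phase > np.pi + 1e-9) or np.any(phase <= -np.pi - 1e-9):
        raise FormatError(
            "phase values outside (-pi, pi]; wrap the phase to the principal "
            "interval before writing"
        )
    side = read_sidecar(out_dir / f"{prefix}_sidecar.yaml")
    geometry: AcquisitionGeometry = side["geometry"]
    if not np.allclose(vox_m, geometry.voxel_size_mm, atol=1e-6):
        raise FormatError(
            f"voxel sizes {tuple(vox_m)} do not match sidecar geometry "
            f"{geometry.voxel_size_mm}"
        )
    return ComplexVolumeSeries(mag, phase, np.asarray(side["timestamps_s"]), geometry)


def write_temperature_series(out_dir, temps: TemperatureSeries,
                             prefix: str = "temperature") -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "temperature": out_dir / f"{prefix}.nii",
        "validity": out_dir / f"{prefix}_valid.nii",
        "sidecar": out_dir / f"{prefix}_sidecar.yaml",
    }
    write_series(paths["temperature"], temps.temperature, temps.geometry, "degC")
    write_series(paths["validity"], temps.valid.astype(np.float64), temps.geometry,
                 "validity mask")
    write_sidecar(paths["sidecar"], temps.geometry, temps.timestamps)
    return paths


def read_temperature_series(out_dir, prefix: str = "temperature") -> TemperatureSeries:
    out_dir = Path(out_dir)
    temp, _, _ = read_series(out_dir / f"{prefix}.nii")
    valid, _, _ = read_series(out_dir / f"{prefix}_valid.nii")
    side = read_sidecar(out_dir / f"{prefix}_sidecar.yaml")
    return TemperatureSeries(temp, valid > 0.5, np.asarray(side["timestamps_s"]),
                             side["geometry"])


def write_dose_map(out_dir, dose: ThermalDoseMap, prefix: str = "dose") -> dict:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cem43": out_dir / f"{prefix}_cem43.nii",
        "coverage": out_dir / f"{prefix}_coverage.nii",
    }
    write_volume(paths["cem43"], dose.cem43, dose.geometry, "minutes (CEM43)")
    write_volume(paths["coverage"], dose.coverage, dose.geometry, "coverage mask")
    return paths
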