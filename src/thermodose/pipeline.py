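"""End-to-end orchestration: simulate -> reconstruct -> dose -> segment -> agree.

A ``PipelineConfig`` fully determines a run; every stochastic stage
derives its substream deterministically from the master seed, so
re-running an identical config reproduces identical output checksums.
Stage failures are recorded in the run manifest and do not abort
independent later stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from . import io_nifti, synthetic
from .agreement import cohort_report
from .containers import TemperatureSeries
from .dosimetry import DoseParams, accumulate_cem43, lethal_mask
from .errors import ThermodoseError, UsageError
from .geometry import AcquisitionGeometry
from .segmentation import mask_volume, segment_lesion
from .thermometry import (
    PRFModel,
    build_baseline_library,
    default_background_mask,
    reconstruct_free_breathing,
    reconstruct_gated,
)

logger = logging.getLogger(__name__)


@dataclass
class PhantomConfig:
    preset: str = "gated-13"
    matrix: int = 64
    mode: str = "gated"                    # gated | free_breathing
    heating_duration_s: float = 180.0
    pre_heating_s: float = 60.0
    post_heating_s: float = 120.0
    power_density_w_per_m3: float = synthetic.DEFAULT_POWER_DENSITY_W_PER_M3
    source_sigma_mm: float = synthetic.DEFAULT_SOURCE_SIGMA_MM
    time_step_s: float = 0.25
    snr: float | None = None               # None = noiseless
    motion_amplitude_mm: float = 15.0
    motion_period_s: float = 5.0
    drift: tuple[float, float, float] | None = None
    needle: bool = True


@dataclass
class ReconstructionConfig:
    mode: str | None = None                # default: follow phantom mode
    n_components: int | None = None        # None: 95 % variance, cap 8
    background_radius_mm: float = 25.0
    signal_floor_fraction: float = 0.1


@dataclass
class SegmentationConfig:
    connectivity: int = 26
    search_radius_mm: float = 10.0
    fill_void: bool = True


@dataclass
class CohortConfig:
    n_lesions: int = 27
    median_volume_mm3: float = synthetic.DEFAULT_MEDIAN_VOLUME_MM3
    sigma_log: float = synthetic.DEFAULT_SIGMA_LOG
    expansion_factor: float = 0.0
    noise_cv: float = synthetic.DEFAULT_NOISE_CV
    p_excluded: float = 6.0 / 33.0


@dataclass
class PipelineConfig:
    seed: int = 0
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    reconstruction: ReconstructionConfig = field(default_factory=ReconstructionConfig)
    dose: DoseParams = field(default_factory=DoseParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    prf: PRFModel = field(default_factory=PRFModel)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        kw = {}
        section_types = {f.name: f for f in fields(cls)}
        for name, raw in (doc or {}).items():
            if name not in section_types:
                raise UsageError(f"unknown config section or key: {name!r}")
            f = section_types[name]
            if name == "seed":
                kw[name] = int(raw)
            else:
                typ = {
                    "phantom": PhantomConfig,
                    "reconstruction": ReconstructionConfig,
                    "dose": DoseParams,
                    "segmentation": SegmentationConfig,
                    "cohort": CohortConfig,
                    "prf": PRFModel,
                }[name]
                known = {x.name for x in fields(typ)}
                bad = set(raw) - known
                if bad:
                    raise UsageError(f"unknown keys in section {name!r}: {sorted(bad)}")
                if name == "phantom" and raw.get("drift") is not None:
                    raw = dict(raw, drift=tuple(raw["drift"]))
                kw[name] = typ(**raw)
        return cls(**kw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(json.dumps(self.to_dict())), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()

    def substream(self, k: int) -> int:
        """Deterministic child seed for stage k (always below 2**31)."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(k,))
        return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list
    versions: dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / float(denom) if denom else 1.0


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the full pipeline, writing all stage outputs to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: list[dict] = []

    def record(name: str, status: str, started: float, outputs: dict | None = None,
               **extra) -> None:
        entry = {
            "stage": name,
            "status": status,
            "seconds": round(time.perf_counter() - started, 3),
            "outputs": {
                str(p): _checksum(Path(p)) for p in (outputs or {}).values()
            },
        }
        entry.update(extra)
        stages.append(entry)
        logger.info("stage %s: %s (%.2fs)", name, status, entry["seconds"])

    pc = config.phantom
    geometry = AcquisitionGeometry.preset(pc.preset, matrix=pc.matrix)
    truth = series = temps = dose = None

    # --- simulate -----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        truth = synthetic.make_phantom(
            geometry,
            heating_duration_s=pc.heating_duration_s,
            pre_heating_s=pc.pre_heating_s,
            post_heating_s=pc.post_heating_s,
            power_density_w_per_m3=pc.power_density_w_per_m3,
            source_sigma_mm=pc.source_sigma_mm,
            time_step_s=pc.time_step_s,
            dose_params=config.dose,
        )
        n = truth.temperature_series.n_frames
        trace = (
            synthetic.RespiratoryTrace.constant(n)
            if pc.mode == "gated"
            else synthetic.RespiratoryTrace.sinusoid(
                n, geometry.frame_interval_s, pc.motion_period_s, pc.motion_amplitude_mm
            )
        )
        series, applied = synthetic.synthesize_acquisition(
            truth.temperature_series, geometry, config.prf,
            snr=pc.snr, drift=pc.drift, trace=trace,
            needle=synthetic.NeedleSpec(truth.tip_voxel) if pc.needle else None,
            mode=pc.mode, seed=config.substream(1),
        )
        outputs = io_nifti.write_complex_series(
            out_dir, series, "thermo", config.prf, config.seed
        )
        for name, arr in [("liver", truth.liver), ("needle", truth.needle),
                          ("true_lethal", truth.lethal)]:
            p = out_dir / f"{name}_mask.nii"
            io_nifti.write_volume(p, arr, geometry, "mask")
            outputs[name] = p
        record("simulate", "ok", t0, outputs, seed=config.substream(1),
               tip_voxel=list(truth.tip_voxel))
    except ThermodoseError as e:
        record("simulate", f"failed: {e}", t0)

    # --- reconstruct --------------------------------------------------------
    t0 = time.perf_counter()
    if series is not None:
        try:
            rc = config.reconstruction
            mode = rc.mode or pc.mode
            n_baseline = int(pc.pre_heating_s / geometry.frame_interval_s)
            baseline_frames = np.arange(max(n_baseline, 1))
            if mode == "gated":
                temps = reconstruct_gated(
                    series, baseline_frames, config.prf, rc.signal_floor_fraction
                )
            else:
                library = build_baseline_library(
                    series, baseline_frames, rc.n_components,
                    signal_floor_fraction=rc.signal_floor_fraction,
                )
                bg = default_background_mask(
                    geometry, truth.tip_voxel, rc.background_radius_mm
                )
                temps = reconstruct_free_breathing(series, library, bg, config.prf)
            outputs = io_nifti.write_temperature_series(out_dir, temps)
            record("reconstruct", "ok", t0, outputs, mode=mode)
        except ThermodoseError as e:
            record("reconstruct", f"failed: {e}", t0)
    else:
        record("reconstruct", "skipped: no acquisition", t0)

    # --- dose ---------------------------------------------------------------
    t0 = time.perf_counter()
    if temps is not None:
        try:
            dose = accumulate_cem43(temps, config.dose)
            outputs = io_nifti.write_dose_map(out_dir, dose)
            lm = lethal_mask(dose, config.dose)
            p = out_dir / "lethal_mask.nii"
            io_nifti.write_volume(p, lm, geometry, "mask")
            outputs["lethal"] = p
            record("dose", "ok", t0, outputs,
                   lethal_volume_mm3=mask_volume(lm, geometry))
        except ThermodoseError as e:
            record("dose", f"failed: {e}", t0)
            dose = None
    else:
        record("dose", "skipped: no temperature series", t0)

    # --- segment ------------------------------------------------------------
    t0 = time.perf_counter()
    segment = None
    if dose is not None and truth is not None:
        try:
            sc = config.segmentation
            lm = lethal_mask(dose, config.dose)
            segment = segment_lesion(
                lm, truth.tip_voxel, truth.liver, geometry,
                needle_mask=truth.needle, connectivity=sc.connectivity,
                search_radius_mm=sc.search_radius_mm, fill_void=sc.fill_void,
            )
            p = out_dir / "predicted_lesion.nii"
            io_nifti.write_volume(p, segment.mask, geometry, "mask")
            result = {
                "volume_mm3": segment.volume_mm3,
                "status": segment.status,
                "island_label": segment.island_label,
                "removed_by_liver_clip": segment.removed_by_liver_clip,
                "added_by_void_fill": segment.added_by_void_fill,
                "true_lethal_volume_mm3": truth.lethal_volume_mm3,
                "volume_error_pct": (
                    100.0 * (segment.volume_mm3 - truth.lethal_volume_mm3)
                    / truth.lethal_volume_mm3
                    if truth.lethal_volume_mm3 > 0 else None
                ),
                "dice_vs_truth": _dice(segment.mask, truth.lethal),
            }
            rp = out_dir / "lesion_result.json"
            rp.write_text(json.dumps(result, indent=2))
            extra = {
                ("segment_status" if k == "status" else k): v
                for k, v in result.items()
            }
            record("segment", "ok", t0, {"mask": p, "result": rp}, **extra)
        except ThermodoseError as e:
            record("segment", f"failed: {e}", t0)
    else:
        record("segment", "skipped: no dose map", t0)

    # --- cohort + agreement (lesion-independent) ----------------------------
    t0 = time.perf_counter()
    try:
        cc = config.cohort
        _, cohort = synthetic.generate_cohort(
            cc.n_lesions, cc.median_volume_mm3, cc.sigma_log,
            cc.expansion_factor, cc.noise_cv, cc.p_excluded,
            geometry=geometry, seed=config.substream(2), dose_params=config.dose,
        )
        cp = out_dir / "cohort.csv"
        cohort.to_csv(cp)
        report = cohort_report(cohort)
        rp = out_dir / "agreement_report.json"
        rp.write_text(report.to_json())
        tp = out_dir / "agreement_report.txt"
        tp.write_text(report.to_text())
        record("agree", "ok", t0, {"cohort": cp, "report": rp, "text": tp},
               gaps=report.gaps)
    except ThermodoseError as e:
        record("agree", f"failed: {e}", t0)

    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        stages=stages,
        versions={"numpy": np.__version__},
    )
    (out_dir / "manifest.json").write_text(manifest.to_json())
    return manifest
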