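# thermodose

Real-time MR-thermometry thermal-dose analysis for microwave liver
ablation, as a tested, reusable Python pipeline — with a synthetic
bioheat/MR phantom generator so every stage runs and validates without
patient data.

## The problem

During MR-guided microwave ablation (MWA) of liver tumors, gradient-echo
EPI phase images are streamed in real time and converted to temperature
maps via the proton resonance frequency (PRF) shift: a temperature rise
ΔT changes the phase by

&nbsp;&nbsp;&nbsp;&nbsp;Δφ = 2π · γ̄ · α · B₀ · TE · ΔT = c · ΔT,

with α ≈ −0.01 ppm/°C, so c ≈ −0.0722 rad/°C at 1.5 T and TE = 18 ms.
The time–temperature history is collapsed per voxel into the cumulative
equivalent minutes at 43 °C (Sapareto model),

&nbsp;&nbsp;&nbsp;&nbsp;CEM43 = Σ Δt[min] · R^(43−T),&nbsp;&nbsp;R = 0.5 (T ≥ 43 °C), 0.25 (T < 43 °C),

and tissue at or above 240 equivalent minutes is considered irreversibly
coagulated. The thresholded dose map, cleaned up the way a reading room
would (main island around the antenna, clipped to the liver, needle
signal void filled), is the *thermometry-predicted lesion*; its volume
is compared against the ablation zone segmented on day-1 contrast MRI
with Pearson correlation (Fisher-z CI) and Bland–Altman analysis.

The package covers both acquisition regimes: respiratory-gated imaging
(single-baseline subtraction with temporal phase unwrapping) and free
breathing (multi-baseline correction — integer-voxel registration plus a
per-frame least-squares fit of the background phase on a PCA basis
learned from pre-heating frames).

Who it is for: image-analysis researchers who need a transparent,
testable reference implementation of PRF thermometry → CEM43 dosimetry →
lesion volumetry → agreement statistics, plus a physics-grounded phantom
(Pennes bioheat equation, explicit finite differences) to exercise it.

## Worked example

```python
import numpy as np
import thermodose as td

geometry = td.AcquisitionGeometry.preset("gated-13")   # 13 x 64 x 64, 2 s frames
phantom = td.make_phantom(geometry)                    # 60 s baseline, 180 s emission, 120 s cooling
series, _ = td.synthesize_acquisition(
    phantom.temperature_series, geometry,
    needle=td.NeedleSpec(phantom.tip_voxel), mode="gated", seed=1,
)
temps = td.reconstruct_gated(series, baseline_frames=np.arange(30))
dose = td.accumulate_cem43(temps)
seg = td.segment_lesion(td.lethal_mask(dose), phantom.tip_voxel,
                        phantom.liver, geometry, needle_mask=phantom.needle)
print(f"predicted {seg.volume_mm3:.0f} mm3, truth {phantom.lethal_volume_mm3:.0f} mm3")
```

prints

```
predicted 15805 mm3, truth 16064 mm3
```

i.e. the noiseless gated pipeline recovers the ground-truth lethal
volume to −1.6 % (Dice 0.992); the residual deficit is the rim of the
needle signal void that the dose mask cannot encapsulate. A cohort of
simulated lesions with day-1 observations and the full agreement report:

```python
_, cohort = td.generate_cohort(n_lesions=27, seed=1)
report = td.cohort_report(cohort)
print(report.to_text())
```

The same stages are available from the shell:

```bash
thermodose run-all --out run/            # simulate -> reconstruct -> dose -> segment -> agree
thermodose simulate --preset gated-13 --seed 3 --out sim/
thermodose reconstruct --in-dir sim --mode gated --baseline-frames 0:30 --out rec/
thermodose dose --in-dir rec --out dose/
thermodose segment --lethal dose/lethal_mask.nii --liver sim/liver_mask.nii \
    --needle sim/needle_mask.nii --seed-voxel 6,32,32 --out seg/
thermodose agree --cohort run/cohort.csv --out report.json
```

Volumes and series are NIfTI-1 (time as the 4th dimension, units in the
header), cohorts are CSV, reports and run manifests are JSON; a YAML
config fully determines a `run-all` and identical configs reproduce
identical output checksums.

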