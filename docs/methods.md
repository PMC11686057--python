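# Methods

This note documents the models, the defaults and why they were chosen,
the numerical choices, and what the synthetic phantom does and does not
emulate.

## Forward model: Pennes bioheat phantom

Ground-truth heating solves the Pennes bioheat equation

ρc ∂T/∂t = k ∇²T − w_b c_b (T − T_body) + Q(x, t)

by explicit forward-Euler finite differences on the acquisition grid,
with Dirichlet boundary at body temperature (a zero-flux Neumann option
exists for closed-form comparisons). Defaults are literature-typical
liver values: k = 0.5 W/(m·°C), ρ = 1050 kg/m³, c = 3600 J/(kg·°C),
w_b·c_b = 2000 W/(m³·°C), T_body = 37 °C. The requested time step is
validated against the FTCS stability bound
Δt ≤ 1/(2α Σᵢ 1/hᵢ² + w/ρc) (≈10 s on the default 3.0 × 2.8 × 2.8 mm
grid; the default 0.25 s is far inside it) and then shortened so image
frames fall exactly on step boundaries. The solver is verified against
three independent oracles: the no-forcing identity, the perfusion-only
exponential relaxation, and the free-space heat kernel for a point
excess.

The microwave source is a spatially Gaussian power deposition centred on
the antenna active tip — the simplest source consistent with an
ellipsoidal ablation zone. Clinical generator settings are not modelled;
the defaults (σ = 9 mm, 1.4 × 10⁶ W/m³, 180 s emission bracketed by a
60 s baseline and 120 s cooling) were fixed once to produce a peak near
82 °C and a lethal volume of ≈16,000 mm³, the scale of the clinical
series this emulates. Dose keeps accumulating through the cooling tail.

## MR signal synthesis

Per frame the complex signal is M·exp(iφ) with

φ = φ₀ (smooth anatomical phase, moves with the object)
  + c·ΔT (PRF shift, moves with the object)
  + β·d(t)·P(x) (susceptibility modulation proportional to displacement)
  + t·(a + b·row + c·col) (linear-in-time, first-order-polynomial B0 drift)
  + complex Gaussian noise (std 1/SNR of the unit mean magnitude),

wrapped to (−π, π]. Magnitude is a smooth positive texture of unit mean
(what registration locks onto) and zero inside the needle cylinder
(radius 5.6 mm — the needle plus directly adjacent voxels give no
signal). Respiratory motion is a rigid craniocaudal sinusoid (default
15 mm amplitude, 5 s period, within the 10–40 mm range typical of the
liver), applied by integer-voxel resampling: displacement is quantized
to the voxel grid, consistent with the translation-only, integer-voxel
registration downstream; sub-voxel motion and deformation are out of
scope. The returned trace records the applied displacement.

What the phantom does *not* emulate: k-space/EPI artifacts, multi-coil
reconstruction, deformable motion, temperature-dependent tissue
properties, electromagnetic antenna physics (SAR). Passing tests
therefore demonstrate correctness of the reconstruction/dosimetry
chain under rigid motion and smooth fields, not robustness to every
clinical artifact — the clinical series itself saw 18 % of lesions
excluded for artifacts.

## Temperature reconstruction

PRF constants: α = −0.01 ppm/°C, γ̄ = 42.577 MHz/T, T₀ = 37 °C
(standard literature values; with B₀ = 1.5 T, TE = 18 ms the coefficient
is c ≈ −0.0722 rad/°C, i.e. a single-step ambiguity of π/|c| ≈ 43 °C).

**Gated mode.** The baseline is the complex average of the pre-ablation
gated frames (lower noise than any single frame). Per-frame phase
increments are wrapped to (−π, π] and accumulated, so the total rise may
exceed the single-step ambiguity; a voxel whose increment exceeds
0.95 π is flagged invalid from that frame on rather than silently
unwrapped. Voxels below the signal floor (10 % of the median baseline
magnitude — needle void, air) are invalid in every frame and contribute
no dose; invalid temperatures are reported as T₀, never NaN.

**Free-breathing mode.** A baseline library is learned from ≥5
pre-heating frames spanning the respiratory cycle: each frame is
registered to the first library frame, phase deviations from the
circular mean are decomposed by PCA, and the default component count is
the smallest explaining 95 % of the library variance, capped at 8. Per
reconstruction frame: (1) integer-voxel translation registration of the
magnitude to the library reference — normalized cross-correlation of
the reference's interior template, assembled from 2D projections (the
in-plane shift first, then the slice shift after compensating it),
which is unbiased under the edge effects that breathing translation
creates; (2) least-squares fit of the registered phase deviation on
{constant, components} over a background mask (default: valid voxels
farther than 25 mm from the antenna tip — the heated neighbourhood must
not be fitted); (3) temperature from the temporally-unwrapped fit
residual. A singular fit (background mask too small) marks the frame
invalid instead of raising. Reconstructed maps live in the reference
frame's object position — comparisons against object-frame truth must
account for the reference displacement.

## Dosimetry and segmentation

CEM43 uses R = 0.5 at and above 43 °C (the standard convention; the
boundary value is not distinguishable in practice) and 0.25 below, with
no low-temperature cutoff — sub-39 °C contributions are negligible by
construction. Temperature is held piecewise constant per frame
(left-endpoint hold over the inter-frame interval; the final frame is
held for the preceding interval), matching a 2 s real-time stream.
Streaming and batch accumulation are the same code path and bitwise
identical. The lethal threshold is inclusive (CEM43 ≥ 240 min).

Segmentation order is part of the contract: threshold → island
selection → liver clip → void fill. Island selection uses
26-connectivity; if the seed sits in the needle void the nearest
component within 10 mm is chosen (ties: larger component, then lowest
label), and an empty result carries an explicit status instead of
raising. Void filling fills 3D-enclosed cavities and adds needle voxels
the mask's filled hull encapsulates; "encapsulated" is implemented as
being flood-fill-enclosed in some axis-aligned cross-sectional plane,
which captures a tunnel that opens to the volume edge along its own
axis but is ringed by dose radially, while excluding the shaft outside
the lesion. Volume is voxel counting (count × 23.52 mm³ at default
geometry); mesh-based estimates are out of scope.

For lesions that are small relative to the 5.6 mm void radius the rim
of the needle tunnel is not recoverable and the predicted volume is
biased low; at the default phantom scale the end-to-end bias is about
−1.6 % with Dice 0.99.

## Cohort model and agreement statistics

True lethal volumes are lognormal with median 16,296 mm³ and log-SD
0.33 (matching the reported median and IQR of the predicted volumes);
day-1 ablation-zone volumes are true × (1 + expansion) × lognormal noise
of unit mean. Defaults: expansion 0 (the reported day-1 median equals
the predicted median), noise CV 0.1556, fixed once so the generative
raw-scale correlation is 0.90 — the closed form for correlated
lognormals, together with its inverse, is provided
(`generative_correlation`, `noise_cv_for_correlation`). Grades and
subgroup flags are drawn from the reference cohort frequencies
(`thermodose.reference`). Cohort phantom cases are lightweight
volumetric stand-ins (ellipsoidal lethal masks with a synthetic,
monotonically decaying CEM43 field), not physics runs.

Statistics follow the conventions of the clinical report this mirrors:
Pearson r with the Fisher-z interval tanh(atanh r ± z/√(n−3)) and the
two-sided t-based p; Bland–Altman with sample SD and 1.96·SD limits;
independent-samples Fisher-z comparison of subgroup correlations
(lesion-level clustering ignored); a two-sided Fisher exact test summing
hypergeometric probabilities ≤ the observed table's; grade summaries
with the sample (n−1) SD. Printed renderings truncate rather than round
(85.185 % → "85.1"), reproducing the reference report's convention;
full precision is always reported alongside.

One calibration subtlety: the Fisher-z interval attains nominal coverage
under bivariate normality. The generator is exactly bivariate Gaussian
on the log scale, where the coverage test operates (93–97 % band at
n = 27); on the raw, right-skewed volume scale the interval runs a few
points below nominal at r ≈ 0.9 — a known small-sample property of the
transform, not an implementation artifact.

## Problem sizes and determinism

Default analysis sizes were chosen so every stage is exercised at
clinically meaningful scale while remaining quick on one CPU: a
64 × 64 × 13 gated grid with 181 frames for the end-to-end phantom, a
48 × 48 × 20 free-breathing phantom (24 library + 16 heated frames) for
the motion-correction studies, 27-lesion cohorts with up to 500
Monte-Carlo replicates for statistical calibration. Every stochastic
stage derives its substream deterministically from a single master seed
(`SeedSequence(seed, spawn_key)`), and all generators are bitwise
reproducible given (seed, parameters); pipeline runs with identical
configs produce identical output checksums.

## Known limitations

- Translation-only, integer-voxel motion model and registration; no
  deformation, through-plane rotation or sub-voxel refinement.
- Single-echo PRF without fat suppression; referenceless and multi-echo
  variants are out of scope.
- The vendor software's exact PRF constants, PCA configuration and
  fit masks are not public; this package fixes documented defaults
  rather than guessing them.
- Whether the clinical dose threshold was strict (">240") or inclusive
  is not documented; this package uses ≥ 240 min.
- Arrhenius damage models and dose-uncertainty propagation are not
  implemented.
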