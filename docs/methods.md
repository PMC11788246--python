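# Methods

This note records the models implemented in `thermoflow`, the parameter
choices that matter, what the synthetic phantom does and does not emulate,
and the numerical decisions a maintainer would want to know about.

## PRF thermometry

The temperature map is computed from the phase difference between the
current registered frame and the reference frame:

    ΔT = wrap(φ_t − φ_ref) / (2π · γ_Hz · σ · TE · B0)

with γ = 42.58 MHz/T, σ = −0.0094 ppm/°C (negative: heating lowers the
water resonance), and defaults TE = 18 ms, B0 = 1.5 T.  Note the explicit
2π: with phase measured in radians and γ expressed in Hz/T it is
dimensionally required.  Compact notations of the PRF relation often leave
it implicit; this implementation fixes phase-in-radians and includes it
throughout, giving ≈ −0.0679 rad/°C (≈ −14.7 °C per radian) at the default
parameters.

Because ±π of phase difference corresponds to only about ±46 °C here, a
50 °C ablation wraps.  `temporal_unwrap` removes 2π jumps along time per
voxel; it assumes the true frame-to-frame phase change stays below π, which
holds comfortably at clinical heating rates and 2–5 s frame intervals.

### Drift correction

Scanner field drift adds a slowly varying phase offset.  Per frame and per
slice a first-order 2D polynomial (offset + row/column ramps) is fitted
over unheated in-body voxels and subtracted everywhere.  The exact
spatial-temporal form used by clinical online implementations is not
standardized; a per-frame first-order spatial fit is the declared stand-in
here.  Voxels are excluded from the fit once their *corrected* |ΔT|
exceeded 3 °C at any earlier frame, so genuine heating is never regressed
away; using the corrected estimate for the exclusion matters, because an
uncorrected global drift would eventually push every voxel over the
threshold and starve the fit.  Frames with fewer than 50 usable voxels are
left uncorrected with a warning.

### Temporal filtering

A causal (not zero-phase) first-order Butterworth low-pass with a 0.14 Hz
cutoff runs along time per voxel, initialized at the first sample so a
constant passes unchanged.  Causality matches the real-time display
setting; the digital design matches the analog magnitude response exactly
at the cutoff (gain 1/√2).  Gated series with irregular timestamps use the
mean frame interval for the coefficient — Table-level jitter (≲ 10% of the
interval) moves the cutoff negligibly.

## Registration

### Horn–Schunck (conventional)

Slice-wise 2D estimation in the pull-back convention
`moving(x + F(x)) ≈ reference(x)`; `u` shifts columns, `v` rows, in voxels.
The classic data + α²·smoothness objective is solved by Jacobi sweeps with
the standard 12-point neighbourhood average, coarse-to-fine over a
3-level pyramid (downscale ×2) with three re-warps per level and up to 100
iterations per warp (early exit when the mean update < 1e−3 voxel).
Defaults: α = 0.1 on unit-normalized intensities — weak enough to follow
genuine deformation, which is precisely why heating artifacts leak into
the flow (the effect the PCA variant exists to fix).  Both images are
presmoothed with a σ = 1 voxel Gaussian before differentiation, standard
optical-flow practice that keeps pixel noise out of the
brightness-constancy derivatives; without it the learning-phase flows of a
noisy but motionless series inherit a common bias from the reference
frame's noise realization.

### PCA-constrained flow

During the preparative learning phase (default: frames 0–14, breathing
only, no heating) Horn–Schunck flows are collected against the reference
frame and a PCA of the mean-removed flattened (u, v) fields yields
orthonormal eigen-flows.  The smallest number of components reaching 95%
explained variance is kept, capped at 5 — small k *is* the method's
regularization.  From the first intervention frame (index 15) on, the flow
is `mean + Σ a_k · component_k` with coefficients solving the linearized
brightness-constancy least squares in the k-dimensional subspace:
Gauss–Newton with re-warping, each voxel weighted by its local gradient
magnitude, a k×k normal system per iteration (10 iterations or Δa < 1e−4).
The solution is the best subspace fit regardless of whether breathing
drifts outside the learned range — no anchoring to the mean flow.

Slices are estimated independently (the method is 2D slice-to-slice;
through-plane motion is out of scope), but one basis concatenates all
slices so the descriptors are global.

### Reference position

The reference frame is the one whose scalar position (spatial mean of the
flow against frame 0, along the dominant motion axis) is the lower median
of the first 10 frames — near end-exhale for gated acquisitions, mid-cycle
for fixed-frequency ones, minimizing the displacements to estimate.  Ties
resolve to the earliest frame.  The standard workflow performs no
registration at all and defaults to frame 0 unless an index is supplied.

## Susceptibility phase correction

Breathing moves tissue through a spatially varying field, so even
perfectly registered phase varies with motion state.  Per voxel the
registered, temporally unwrapped phase (relative to the reference frame)
is modeled as affine in a small motion-descriptor vector — the flow's
coefficients on the eigen-flow basis, so both optical-flow workflows share
one model form (the conventional flow is projected onto the same basis).
Ordinary least squares over the learning frames gives an intercept map and
one coefficient map per descriptor; at most 3 descriptors are used for the
phase model (beyond that the learning frames overfit).  The model is
frozen after the learning phase: refitting during heating would absorb the
PRF signal itself.  The fit requires at least k+1 learning frames and is
invariant to constant descriptor offsets (absorbed by the intercept).

## Dosimetry

Sapareto–Dewey cumulative equivalent minutes at 43 °C:
`CEM43 = Σ R^(43 − T) · Δt_min`, R = 0.5 at or above 43 °C, 0.25 below
(the canonical constants; exposed in the API), absolute temperature =
37 °C baseline + ΔT.  Dose integrates the drift-corrected, filtered
temperature series — the pipeline's final output, matching the processing
order register → susceptibility-correct → temperature → unwrap → drift →
filter → dose.  Frames whose warp sampled out of bounds contribute zero
dose (conservative), and dose is undefined (NaN) outside the body mask,
where phase is pure noise.  The lesion mask is CEM43 ≥ 240 min — the
conventional cell-death threshold — and the lesion volume is the voxel
count times voxel volume in cm³.  No temperature ceiling is applied before
accumulation.

## The synthetic phantom

The generator emulates the acquisition regimes the pipeline targets:

* **Template**: smooth random liver-like texture with four dark
  vessel-like streaks inside a soft-edged elliptical body; smooth random
  baseline phase (σ ≈ 0.5 rad, ~10-voxel correlation length).
* **Motion**: dominant head–foot translation scaled by a Gaussian spatial
  envelope (range 0.5–1), making the field non-rigid; the temporal profile
  `((1 − cos τ)/2)²` spends most of the cycle near end-exhale, as in
  ventilated quiet breathing.  Default amplitude 4 voxels, respiratory
  period 4.7 s.  Gated mode samples end-exhale with a half-normal residual
  jitter (default 0.3 voxel); fixed-frequency mode strides the cycle at
  the frame interval (default 2 s, i.e. 0.5 Hz).
* **Heating**: Gaussian hotspot (σ = 3 voxels in-plane, twice as fast
  through-slice) with a saturating-exponential rise over the heating
  window and exponential cool-down; peak 50 °C by default.  The PRF phase
  of the true temperature is added in tissue coordinates.
* **Signal dropout**: multiplicative Gaussian well time-locked to the
  heating profile, default 50% peak drop — the failure mode that derails
  conventional flow.
* **Susceptibility**: background phase gain of 0.1 rad per voxel of local
  displacement.  No quantitative in-vivo value is established for this
  coupling; 0.1 rad/voxel makes the uncorrected motion-phase error worth
  several °C at 4-voxel breathing — large enough to be consequential,
  small enough to stay within a fraction of a wrap.
* **Noise and drift**: additive complex Gaussian noise (2% of mean body
  magnitude, hence Rician magnitude statistics) before magnitude/phase
  extraction, and a global phase drift of 0.005 rad/frame.

Ground truth stores the exact per-frame registration flow (obtained by
fixed-point inversion of the analytic forward displacement, so it lives in
the estimators' own pull-back convention), the true ΔT at the template
grid, and the lesion mask from dosimetry of the true temperatures.
Helpers re-express truth at the grid of whichever frame the pipeline
selects as reference.

What the phantom does **not** model: through-plane motion, gas-bubble
susceptibility transients, B1/coil shading, the post-ablation hyperintense
rim, k-space/EPI reconstruction artifacts, and spontaneous organ
contraction.  Passing tests therefore demonstrate correctness of the
algorithms under in-plane breathing with heating-locked dropout, not
robustness to every clinical artifact.

## Problem sizes

The test suite and the acceptance script run single-slice 96×96 or 128×128
phantoms with 60–140 frames — large enough for 19×19 evaluation ROIs,
multi-cycle learning phases and wrap-inducing 50 °C heating, while a full
three-workflow comparison completes in seconds.  The `gated_paper` /
`fixed_frequency_paper` presets carry the clinical geometry (13 slices,
128×128, 2.5×2.5×3 mm, 180–350 repetitions) for users who want
protocol-scale runs.

## Known limitations

* Horn–Schunck parameters are exposed but not auto-tuned; strongly
  textureless regions rely entirely on the smoothness term.
* The susceptibility model is first-order in the descriptors; strongly
  nonlinear motion-phase coupling (e.g. near gas interfaces) is not
  captured.
* Temporal unwrapping is best-effort: a per-frame temperature jump beyond
  ~46 °C between consecutive frames would alias.
* The drift fit assumes enough unheated body voxels per slice; tiny
  fields of view with large lesions may skip correction (a warning is
  emitted).
* DICOM ingestion expects per-frame AcquisitionNumber/AcquisitionTime
  tags and the common stored-phase convention ([0, 4096) linear to
  [−π, π)); other dialects need the explicit `(slope, intercept)`
  override.
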