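# thermoflow

Motion-compensated PRF MR thermometry for MRI-guided thermal ablation of
abdominal organs.

During microwave or laser ablation of a liver tumor, MR phase images let the
interventionalist watch tissue temperature in real time: the water proton
resonance frequency (PRF) shifts linearly with temperature, so the phase
difference between a dynamic image and a pre-heating reference maps to a
temperature change per voxel.  Two things break this on a breathing patient:

1. **Respiratory motion** displaces the liver by several voxels between
   frames, so phase must be registered back to a fixed reference position and
   the motion-dependent background (susceptibility) phase removed.
2. **Heating itself changes tissue MR properties**, dropping the magnitude
   signal by 50–80% around the applicator.  A conventional optical-flow
   registration reads that intensity change as motion and produces spurious
   displacement fields exactly where the temperature matters most, corrupting
   the temperature, the accumulated thermal dose and the predicted lesion
   size.

`thermoflow` implements and compares three thermometry workflows:

* **standard** — fixed-reference phase subtraction (the gold standard when
  acquisition is respiratory-gated and the organ truly holds still);
* **conventional_of** — per-frame Horn–Schunck optical-flow registration
  plus motion-parameterized susceptibility phase correction;
* **pca_of** — the same learning phase, but during the intervention the flow
  is constrained to a linear combination of eigen-motions (PCA of the flows
  observed during a preparative breathing-only period).  A localized
  heating artifact cannot be expressed in that subspace, so the motion
  estimate — and everything downstream — stays clean.

It ships with a synthetic phantom generator (breathing liver-like template,
PRF-consistent hotspot, heating-locked signal dropout, motion-coupled
susceptibility phase, complex noise, drift) with exact ground truth for
motion, temperature and lesion masks, plus the full evaluation-metric suite
(intercorrelation, NRMSE, endpoint error, Bland–Altman lesion-volume
agreement).

## The model in brief

**PRF temperature.**  With phase in radians,

    ΔT = wrap(φ_t − φ_ref) / (2π · γ · σ · TE · B0),

γ = 42.58 MHz/T, σ = −0.0094 ppm/°C, and by default TE = 18 ms, B0 = 1.5 T,
giving ≈ −14.7 °C per radian.  Heating beyond ~46 °C wraps the phase
difference; a temporal unwrapper restores it.  Drift is removed by a
per-frame first-order spatial polynomial fitted over unheated voxels, and a
causal first-order Butterworth low-pass (0.14 Hz cutoff) suppresses residual
respiratory fluctuation.

**Registration.**  Horn–Schunck minimizes the brightness-constancy residual
plus an α²-weighted smoothness term, solved coarse-to-fine with warping.
The PCA variant solves the same data term restricted to
`mean_flow + Σ a_k · eigenflow_k`, a k-dimensional Gauss–Newton fit
(k ≤ 5 typically).  Phase images are warped through their complex
representation so interpolation never crosses the phase wrap.

**Susceptibility correction.**  Per voxel, the registered phase is modeled
as an affine function of the flow's basis coefficients (ordinary least
squares over the learning frames, frozen afterwards); the predicted
background phase is subtracted before the PRF conversion.

**Dosimetry.**  Sapareto CEM43 = Σ R^(43−T)·Δt with R = 0.5 above 43 °C and
0.25 below; voxels reaching 240 equivalent minutes count as lesion, reported
in cm³ via the voxel geometry.

## Worked example

```bash
python examples/run_thermometry_workflows.py
```

runs all three workflows on a gated phantom with a 50% heating signal drop
and prints:

```
reference frame: 6, ROI center: (0, 48, 48), heating window (frames): (23, 60)
true lesion volume: 1.26 cm³

workflow          T NRMSE med (°C)  lesion (cm³)  volume bias (cm³)
standard                      0.98          1.22              -0.04
conventional_of               7.41          0.68              -0.58
pca_of                        0.84          1.20              -0.06
```

Reading: on a motion-frozen acquisition the fixed-reference subtraction is
the gold standard (~1 °C error from noise).  The conventional-flow workflow
misreads the signal drop as motion — a median 7.4 °C temperature error in
the ablation ROI and a lesion volume underestimated by ~0.6 cm³ (nearly half
the true volume).  The PCA-constrained workflow matches the gold standard on
the same input.  `examples/simulate_phantom.py`, `examples/flow_failure_mode.py`
and `examples/dosimetry_basics.py` walk through the generator, the
registration failure mode, and the dose model.

A thin CLI wraps the same library calls:

```bash
thermoflow simulate --preset fixed_frequency_paper --seed 1 --out sim/
thermoflow run --input sim/ --method pca_of --te 0.018 --b0 1.5 --out out/
thermoflow evaluate --results out/ --truth sim/ --out report/
```

## Layout

| path | contents |
| --- | --- |
| `src/thermoflow/series.py` | `DynamicSeries` container, phase wrapping |
| `src/thermoflow/io.py` | NIfTI/DICOM reading, NIfTI map writing |
| `src/thermoflow/synth.py` | phantom generator with ground truth |
| `src/thermoflow/flow.py` | Horn–Schunck and PCA-constrained optical flow |
| `src/thermoflow/phasecorr.py` | motion-parameterized susceptibility model |
| `src/thermoflow/thermo.py` | PRF conversion, unwrap, drift, low-pass |
| `src/thermoflow/dose.py` | CEM43 accumulation, lesion volume, timing |
| `src/thermoflow/metrics.py` | intercorrelation, NRMSE, EE/AEE, Bland–Altman |
| `src/thermoflow/pipeline.py` | the three workflows and their comparison |
| `src/thermoflow/cli.py` | `thermoflow simulate / run / evaluate` |

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
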