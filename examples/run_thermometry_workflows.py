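"""Run the three thermometry workflows end to end on a gated phantom
with heating-induced signal dropout and compare them to ground truth.

The conventional-flow workflow misreads the signal drop as motion and
underestimates both temperature and lesion volume; the PCA-constrained
workflow tracks the gold standard.
"""

import warnings

import thermoflow as tf

cfg = tf.PhantomConfig(
    grid=(1, 96, 96), n_frames=60, mode="gated",
    displacement_amplitude=0.0, gating_jitter=0.3,
    heating_window=(20, 50), peak_delta_t=50.0, max_signal_drop=0.5,
    seed=1,
)
series, truth = tf.generate_series(cfg)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = tf.compare_workflows(
        series,
        [tf.WorkflowConfig(method=m)
         for m in ("standard", "conventional_of", "pca_of")],
        ground_truth=truth,
    )

print(f"reference frame: {report['reference_index']}, "
      f"ROI center: {report['roi_center']}, "
      f"heating window (frames): {report['heating_window']}")
print(f"true lesion volume: {report['reference_final_volume_cm3']:.2f} cm³\n")
print(f"{'workflow':<16} {'T NRMSE med (°C)':>17} {'lesion (cm³)':>13} "
      f"{'volume bias (cm³)':>18}")
for name, entry in report["workflows"].items():
    print(f"{name:<16} {entry['temperature_nrmse_summary']['median']:>17.2f} "
          f"{entry['final_lesion_volume_cm3']:>13.2f} "
          f"{entry['lesion_volume_bland_altman']['bias']:>18.2f}")
print("\nT NRMSE is the per-frame temperature RMSE over the ablation ROI")
print("(19x19 voxels, >10 °C) against ground truth; the volume bias is the")
print("Bland–Altman bias of the lesion-volume series over the last frames.")
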