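"""End-to-end thermometry workflows and their comparison.

Three workflows share one processing spine
(register → susceptibility-correct → temperature → unwrap → drift →
filter → dose) and differ in how the reference phase is obtained:

``standard``
    Fixed-reference phase subtraction, no registration.  Valid only when
    the acquisition itself froze the motion (gated); the gold standard in
    that regime.
``conventional_of``
    Per-frame Horn–Schunck registration to the reference position plus
    the motion-parameterized susceptibility phase correction.
``pca_of``
    The same learning phase (Horn–Schunck flows on the preparative
    frames, eigen-flow basis, susceptibility fit), then PCA-constrained
    flow estimation from the first intervention frame on.

Both optical-flow workflows share one susceptibility model form: the
motion descriptors are the coefficients of the frame's flow on the
learned eigen-flow basis (for conventional flow, its projection onto
that basis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dose import DoseMap, accumulate_cem43, build_dose_map, lesion_volume
from .flow import (
    FlowBasis,
    FlowField,
    HSParams,
    PCAFlowParams,
    build_flow_basis,
    estimate_flow_hs,
    estimate_flow_pca,
    select_reference_frame,
    warp_image,
)
from .metrics import bland_altman, nrmse, roi_from_temperature, temperature_error
from .phasecorr import (
    SusceptibilityModel,
    fit_susceptibility_model,
    predict_background_phase,
)
from .series import DynamicSeries
from .thermo import (
    TemperatureSeries,
    ThermometryParams,
    drift_correct,
    lowpass_filter,
    temporal_unwrap,
)

logger = logging.getLogger(__name__)

__all__ = ["WorkflowConfig", "WorkflowResult", "run_workflow", "compare_workflows"]

METHODS = ("standard", "conventional_of", "pca_of")


@dataclass
class WorkflowConfig:
    """Everything a workflow run depends on."""

    method: str = "pca_of"
    learning_frames: int = 15
    reference_window: int = 10
    thermometry: ThermometryParams = field(default_factory=ThermometryParams)
    hs_params: HSParams = field(default_factory=HSParams)
    pca_params: PCAFlowParams = field(default_factory=PCAFlowParams)
    variance_threshold: float = 0.95
    max_components: int = 5
    max_phase_descriptors: int = 3
    drift_exclusion_threshold: float = 3.0
    drift_min_voxels: int = 50
    filter_cutoff: float = 0.14
    apply_drift_correction: bool = True
    apply_lowpass: bool = True
    dose_threshold: float = 240.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected {METHODS}")
        if self.learning_frames < self.reference_window:
            raise ValueError("learning_frames must be >= reference_window")


@dataclass
class WorkflowResult:
    """Outputs of one workflow run."""

    method: str
    reference_index: int
    temperature: TemperatureSeries
    cem43: np.ndarray  # (n_frames, z, r, c) cumulative dose
    dose_map: DoseMap
    flows: list[FlowField] | None
    coefficients: np.ndarray | None  # (n_frames, k) descriptors
    basis: FlowBasis | None
    susceptibility: SusceptibilityModel | None
    registered_magnitude: np.ndarray | None
    magnitude_nrmse: np.ndarray  # per frame, vs reference magnitude
    body_mask: np.ndarray

    def lesion_volume_series(
        self, voxel_spacing: tuple[float, float, float]
    ) -> np.ndarray:
        """Lesion volume (cm³) at every frame."""
        return np.array(
            [lesion_volume(self.cem43[t], voxel_spacing, self.dose_map.threshold)
             for t in range(self.cem43.shape[0])]
        )


def _body_mask(ref_mag: np.ndarray) -> np.ndarray:
    return ref_mag > 0.25 * np.percentile(ref_mag, 95)


def run_workflow(
    series: DynamicSeries,
    config: WorkflowConfig,
    reference_index: int | None = None,
) -> WorkflowResult:
    """Run one thermometry workflow end to end.

    ``reference_index`` overrides the automatic median-position reference
    selection (the ``standard`` workflow, which never performs
    registration, defaults to frame 0 when no index is given).
    """
    n = series.n_frames
    if n <= config.learning_frames:
        raise ValueError(
            f"series has {n} frames; need more than learning_frames="
            f"{config.learning_frames}"
        )
    method = config.method
    if method == "standard":
        ref_idx = reference_index if reference_index is not None else 0
    else:
        ref_idx = (
            reference_index
            if reference_index is not None
            else select_reference_frame(series, config.reference_window)
        )
    ref_mag, ref_phase = series.frame(ref_idx)
    body = _body_mask(ref_mag)
    grid = series.grid_shape

    corrected = np.empty((n,) + grid)
    valid = np.ones((n,) + grid, dtype=bool)
    mag_err = np.empty(n)
    flows: list[FlowField] | None = None
    coeffs: np.ndarray | None = None
    basis: FlowBasis | None = None
    model: SusceptibilityModel | None = None
    reg_mag: np.ndarray | None = None

    if method == "standard":
        for t in range(n):
            corrected[t] = np.angle(
                np.exp(1j * (series.phase[t] - ref_phase))
            )
            mag_err[t] = nrmse(series.magnitude[t], ref_mag)
            logger.info(
                "frame %d method=standard nrmse=%.4g", t, mag_err[t]
            )
    else:
        learn = config.learning_frames
        flows = []
        reg_mag = np.empty((n,) + grid)
        # --- learning phase: conventional flow on breathing-only frames
        for t in range(learn):
            if t == ref_idx:
                flows.append(FlowField.zeros(grid))
            else:
                flows.append(
                    estimate_flow_hs(series.magnitude[t], ref_mag, config.hs_params)
                )
        basis = build_flow_basis(
            flows[:learn], config.variance_threshold, config.max_components
        )
        kd = min(basis.n_retained, config.max_phase_descriptors)
        learn_desc = np.stack(
            [basis.project(flows[t])[:kd] if kd else np.zeros(0) for t in range(learn)]
        )
        dphi_learn = np.empty((learn,) + grid)
        for t in range(learn):
            cplx, ok = warp_image(series.complex_frame(t), flows[t])
            reg_mag[t] = np.abs(cplx)
            valid[t] = ok
            dphi_learn[t] = np.angle(cplx * np.exp(-1j * ref_phase))
        dphi_learn = temporal_unwrap(dphi_learn, axis=0)
        if kd > 0 and learn >= kd + 1:
            model = fit_susceptibility_model(dphi_learn, learn_desc)
        # --- all frames: estimate flow, register, subtract background
        coeffs = np.zeros((n, basis.n_retained))
        for t in range(n):
            if t < learn:
                flow = flows[t]
                a = basis.project(flow)
            elif method == "conventional_of":
                flow = estimate_flow_hs(
                    series.magnitude[t], ref_mag, config.hs_params
                )
                flows.append(flow)
                a = basis.project(flow)
            else:  # pca_of
                flow, a = estimate_flow_pca(
                    series.magnitude[t], ref_mag, basis, config.pca_params
                )
                flows.append(flow)
            coeffs[t, : len(a)] = a
            cplx, ok = warp_image(series.complex_frame(t), flow)
            reg_mag[t] = np.abs(cplx)
            valid[t] = ok
            dphi = np.angle(cplx * np.exp(-1j * ref_phase))
            if model is not None:
                background = predict_background_phase(model, coeffs[t, :kd])
                dphi = np.angle(np.exp(1j * (dphi - background)))
            corrected[t] = dphi
            mag_err[t] = nrmse(reg_mag[t], ref_mag, mask=body)
            logger.info(
                "frame %d method=%s |flow|=%.3f coeffs=%s nrmse=%.4g",
                t, method, float(np.mean(flow.magnitude())),
                np.array2string(coeffs[t], precision=2), mag_err[t],
            )

    if method == "standard":
        for t in range(n):
            mag_err[t] = nrmse(series.magnitude[t], ref_mag, mask=body)

    # shared tail: unwrap -> temperature -> drift -> filter -> dose
    unwrapped = temporal_unwrap(corrected, axis=0)
    delta_t = unwrapped / config.thermometry.rad_per_degree
    if config.apply_drift_correction:
        delta_t = drift_correct(
            delta_t,
            body_mask=body,
            exclusion_threshold=config.drift_exclusion_threshold,
            min_voxels=config.drift_min_voxels,
        )
    if config.apply_lowpass:
        delta_t = lowpass_filter(
            delta_t, series.frame_interval, cutoff=config.filter_cutoff
        )
    # outside the body the phase is pure noise; temperatures there are
    # meaningless, so they carry no validity and no dose
    valid &= body[None]
    dt_frames = (
        np.concatenate([[series.frame_interval], np.diff(series.timestamps)])
        if n > 1
        else np.array([series.frame_interval])
    )
    cem = accumulate_cem43(
        delta_t,
        dt_frames,
        baseline_temp=config.thermometry.baseline_temp,
        valid_mask=valid,
    )
    cem[:, ~body] = np.nan
    temperature = TemperatureSeries(
        delta_t=delta_t, valid_mask=valid, params=config.thermometry
    )
    return WorkflowResult(
        method=method,
        reference_index=ref_idx,
        temperature=temperature,
        cem43=cem,
        dose_map=build_dose_map(cem, config.dose_threshold),
        flows=flows,
        coefficients=coeffs,
        basis=basis,
        susceptibility=model,
        registered_magnitude=reg_mag,
        magnitude_nrmse=mag_err,
        body_mask=body,
    )


def compare_workflows(
    series: DynamicSeries,
    configs: list[WorkflowConfig],
    ground_truth=None,
    roi_center: tuple[int, int, int] | None = None,
    roi_size: int = 19,
    volume_frames: int = 10,
    evaluation_frames: int = 100,
) -> dict:
    """Run several workflows on one series and compare them.

    The comparison reference is the synthetic ground truth when given,
    otherwise the ``standard`` (gold standard) workflow, which must then
    be among the configs.  Reported per workflow: per-frame temperature
    NRMSE over the ablation ROI during the heating window, final lesion
    volume, and the Bland–Altman agreement of the lesion-volume series
    (last ``volume_frames`` frames) against the reference.
    """
    if len(configs) < 2:
        raise ValueError("need at least 2 workflows to compare")
    needs_flow_ref = any(c.method != "standard" for c in configs)
    ref_idx = (
        select_reference_frame(series, configs[0].reference_window)
        if needs_flow_ref
        else 0
    )
    results = {
        c.method: run_workflow(series, c, reference_index=ref_idx) for c in configs
    }
    spacing = series.voxel_spacing

    if ground_truth is not None:
        ref_delta_t = ground_truth.delta_t_at_reference(ref_idx)
        dt_frames = np.concatenate(
            [[series.frame_interval], np.diff(series.timestamps)]
        )
        ref_cem = accumulate_cem43(
            ref_delta_t, dt_frames,
            baseline_temp=configs[0].thermometry.baseline_temp,
        )
        ref_volumes = np.array(
            [lesion_volume(ref_cem[t], spacing, configs[0].dose_threshold)
             for t in range(ref_cem.shape[0])]
        )
        reference_name = "ground_truth"
    else:
        if "standard" not in results:
            raise ValueError(
                "no ground truth given and no 'standard' workflow to act as "
                "gold standard"
            )
        gold = results["standard"]
        ref_delta_t = gold.temperature.delta_t
        ref_volumes = gold.lesion_volume_series(spacing)
        reference_name = "standard"

    if roi_center is None:
        peak = np.unravel_index(
            np.argmax(ref_delta_t.max(axis=0)), ref_delta_t.shape[1:]
        )
        roi_center = tuple(int(i) for i in peak)  # type: ignore[assignment]
    roi = roi_from_temperature(roi_center, ref_delta_t, size=roi_size)

    roi_mask = roi.evaluation_mask(series.grid_shape)
    heated_per_frame = np.array(
        [float(np.max(ref_delta_t[t][roi_mask])) if roi_mask.any() else 0.0
         for t in range(series.n_frames)]
    )
    onset_candidates = np.flatnonzero(heated_per_frame > 10.0)
    onset = int(onset_candidates[0]) if onset_candidates.size else 0
    window = (onset, min(onset + evaluation_frames, series.n_frames))

    report: dict = {
        "reference": reference_name,
        "reference_index": ref_idx,
        "roi_center": tuple(roi_center),
        "heating_window": window,
        "n_frames": series.n_frames,
        "frame_interval": series.frame_interval,
        "workflows": {},
    }
    for name, res in results.items():
        per_frame, summary = temperature_error(
            res.temperature.delta_t, ref_delta_t, roi, frames=window
        )
        volumes = res.lesion_volume_series(spacing)
        ba = bland_altman(volumes[-volume_frames:], ref_volumes[-volume_frames:])
        report["workflows"][name] = {
            "temperature_nrmse_per_frame": per_frame,
            "temperature_nrmse_summary": summary,
            "magnitude_nrmse_median": float(np.median(res.magnitude_nrmse)),
            "final_lesion_volume_cm3": float(volumes[-1]),
            "lesion_volume_bland_altman": ba,
            "n_frames_processed": int(res.temperature.n_frames),
        }
    report["reference_final_volume_cm3"] = float(ref_volumes[-1])
    report["results"] = results
    return report
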