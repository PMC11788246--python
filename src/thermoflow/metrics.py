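"""Evaluation metrics: intercorrelation, (N)RMSE, endpoint error,
temperature error and Bland–Altman agreement.

The registration and thermometry comparisons are evaluated on a square
in-plane ROI (default 19 x 19 voxels) centered on the ablated area, and
restricted to the voxels that actually heated (temperature change above
10 °C at any frame), because the heating-induced signal loss — the
failure mode of interest — is confined to the vicinity of the applicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import FlowField

__all__ = [
    "RoiSpec",
    "roi_from_temperature",
    "intercorrelation",
    "nrmse",
    "endpoint_error",
    "temperature_error",
    "bland_altman",
]


@dataclass
class RoiSpec:
    """Evaluation region around the ablation center.

    ``center`` is (slice, row, col); the box spans ``size`` voxels
    in-plane over ``slice_range`` (inclusive); ``inclusion_mask`` flags
    the evaluated voxels inside the box (typically those exceeding the
    heating threshold).
    """

    center: tuple[int, int, int]
    size: int = 19
    slice_range: tuple[int, int] | None = None
    inclusion_mask: np.ndarray | None = field(default=None)

    def box_mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        nz, nr, nc = grid_shape
        z0, r0, c0 = self.center
        half = self.size // 2
        mask = np.zeros(grid_shape, dtype=bool)
        zlo, zhi = self.slice_range if self.slice_range else (0, nz - 1)
        mask[
            max(zlo, 0): min(zhi, nz - 1) + 1,
            max(r0 - half, 0): min(r0 + half, nr - 1) + 1,
            max(c0 - half, 0): min(c0 + half, nc - 1) + 1,
        ] = True
        return mask

    def evaluation_mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        box = self.box_mask(grid_shape)
        if self.inclusion_mask is None:
            return box
        return box & self.inclusion_mask


def roi_from_temperature(
    center: tuple[int, int, int],
    delta_t: np.ndarray,
    size: int = 19,
    threshold: float = 10.0,
    slice_range: tuple[int, int] | None = None,
) -> RoiSpec:
    """Build the ROI whose inclusion mask holds voxels whose temperature
    change exceeded ``threshold`` °C at any frame of ``delta_t``
    (frames, z, r, c)."""
    heated = np.any(np.asarray(delta_t) > threshold, axis=0)
    roi = RoiSpec(center=center, size=size, slice_range=slice_range)
    roi.inclusion_mask = heated & roi.box_mask(heated.shape)
    return roi


def intercorrelation(current: np.ndarray, reference: np.ndarray) -> float:
    """Pearson correlation between two stacks, computed per slice over
    the whole image and averaged over slices.  NaN if any slice has zero
    variance."""
    current = np.asarray(current, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if current.shape != reference.shape:
        raise ValueError("stacks must share one shape")
    if current.ndim == 2:
        current = current[None]
        reference = reference[None]
    coeffs = []
    for z in range(current.shape[0]):
        i = current[z].ravel() - current[z].mean()
        j = reference[z].ravel() - reference[z].mean()
        denom = np.sqrt(np.sum(i**2) * np.sum(j**2))
        if denom == 0:
            return float("nan")
        coeffs.append(float(np.sum(i * j) / denom))
    return float(np.mean(coeffs))


def nrmse(
    current: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
    normalize_by_range: bool = False,
) -> float:
    """Root mean square error sqrt(sum((I-J)^2)/N) over masked voxels.

    Despite the conventional name this is an un-normalized RMSE in the
    units of the inputs; set ``normalize_by_range`` to divide by the
    reference intensity range.
    """
    current = np.asarray(current, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if current.shape != reference.shape:
        raise ValueError("stacks must share one shape")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty mask")
        diff = current[mask] - reference[mask]
        ref_vals = reference[mask]
    else:
        diff = (current - reference).ravel()
        ref_vals = reference.ravel()
    val = float(np.sqrt(np.mean(diff**2)))
    if normalize_by_range:
        rng = float(np.ptp(ref_vals))
        if rng == 0:
            raise ValueError("zero reference range")
        val /= rng
    return val


def endpoint_error(
    flow: FlowField,
    ref_flow: FlowField,
    roi: RoiSpec,
    voxel_spacing: tuple[float, float, float],
) -> tuple[np.ndarray, float]:
    """Endpoint error map (mm) and its average over the ROI inclusion
    mask (AEE).

    EE per voxel is the Euclidean norm of the displacement difference,
    with u scaled by the column spacing and v by the row spacing.
    """
    if flow.grid_shape != ref_flow.grid_shape:
        raise ValueError("flows must share one grid")
    dx, dy, _ = voxel_spacing
    ee = np.sqrt(
        ((flow.u - ref_flow.u) * dx) ** 2 + ((flow.v - ref_flow.v) * dy) ** 2
    )
    mask = roi.evaluation_mask(flow.grid_shape)
    if not mask.any():
        raise ValueError("empty ROI inclusion mask")
    return ee, float(np.mean(ee[mask]))


def temperature_error(
    test: np.ndarray,
    reference: np.ndarray,
    roi: RoiSpec,
    frames: tuple[int, int] | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Per-frame temperature RMSE over the ROI plus a whisker summary.

    ``test`` and ``reference`` are (n_frames, z, r, c) temperature
    stacks; ``frames=(start, stop)`` selects the evaluated window
    (half-open, default: all frames).
    """
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.shape != reference.shape:
        raise ValueError("temperature stacks must share one shape")
    n = test.shape[0]
    start, stop = frames if frames is not None else (0, n)
    if not (0 <= start < stop <= n):
        raise ValueError(f"frame window ({start}, {stop}) outside series of {n}")
    mask = roi.evaluation_mask(test.shape[1:])
    if not mask.any():
        raise ValueError("empty ROI inclusion mask")
    per_frame = np.array(
        [
            np.sqrt(np.mean((test[t][mask] - reference[t][mask]) ** 2))
            for t in range(start, stop)
        ]
    )
    q1, med, q3 = np.percentile(per_frame, [25, 50, 75])
    summary = {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "min": float(per_frame.min()),
        "max": float(per_frame.max()),
        "mean": float(per_frame.mean()),
    }
    return per_frame, summary


def bland_altman(
    volumes_a: np.ndarray, volumes_b: np.ndarray
) -> dict[str, float]:
    """Bland–Altman agreement between paired measurement series.

    Returns bias = mean(a - b) and the 95% limits of agreement
    bias ± 1.96 * sd(a - b).
    """
    a = np.asarray(volumes_a, dtype=float).ravel()
    b = np.asarray(volumes_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=0))
    return {
        "bias": bias,
        "loa_lower": bias - 1.96 * sd,
        "loa_upper": bias + 1.96 * sd,
    }
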