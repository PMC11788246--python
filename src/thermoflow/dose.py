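"""CEM43 thermal dosimetry and lesion-volume estimation.

The Sapareto–Dewey model maps a temperature history onto the cumulative
equivalent minutes at 43 °C:

    CEM43 = sum_t  R^(43 - T(t)) * dt_minutes,
    R = 0.5 for T >= 43 °C, 0.25 below,

and a voxel is counted as lethally ablated once CEM43 reaches 240 min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DoseMap",
    "accumulate_cem43",
    "lesion_volume",
    "time_to_threshold",
    "time_to_threshold_difference",
]

#: Cell-death threshold, equivalent minutes at 43 °C.
LESION_THRESHOLD_CEM43 = 240.0


@dataclass
class DoseMap:
    """Final cumulative dose with derived lesion mask and timing map."""

    cem43: np.ndarray  # (z, r, c) equivalent minutes at 43 °C
    lesion_mask: np.ndarray  # bool, cem43 >= threshold
    time_to_threshold: np.ndarray  # float frame index, NaN where never reached
    threshold: float = LESION_THRESHOLD_CEM43


def accumulate_cem43(
    delta_t: np.ndarray,
    frame_interval: float | np.ndarray,
    baseline_temp: float = 37.0,
    r_below: float = 0.25,
    r_above: float = 0.5,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Cumulative CEM43 per voxel per frame.

    Parameters
    ----------
    delta_t : (n_frames, z, r, c)
        Temperature change above ``baseline_temp`` in °C.
    frame_interval : seconds per frame, scalar or per-frame array.
    valid_mask : optional bool array like ``delta_t``; invalid frames
        contribute zero dose (conservative).

    Returns
    -------
    (n_frames, z, r, c) cumulative dose, non-decreasing along frames.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    dt = np.asarray(frame_interval, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("frame interval must be positive")
    if dt.ndim == 0:
        dt = np.full(delta_t.shape[0], float(dt))
    if dt.shape[0] != delta_t.shape[0]:
        raise ValueError("per-frame intervals must match the frame count")
    temp = baseline_temp + delta_t
    r = np.where(temp >= 43.0, r_above, r_below)
    increments = r ** (43.0 - temp) * dt.reshape((-1,) + (1,) * (delta_t.ndim - 1)) / 60.0
    if valid_mask is not None:
        increments = np.where(valid_mask, increments, 0.0)
    return np.cumsum(increments, axis=0)


def lesion_volume(
    cem43: np.ndarray | DoseMap,
    voxel_spacing: tuple[float, float, float],
    threshold: float = LESION_THRESHOLD_CEM43,
) -> float:
    """Lesion volume in cm³: voxels with dose >= threshold times voxel
    volume (spacing in mm)."""
    dose = cem43.cem43 if isinstance(cem43, DoseMap) else np.asarray(cem43)
    n_above = int(np.sum(dose >= threshold))
    voxel_mm3 = float(np.prod(voxel_spacing))
    return n_above * voxel_mm3 / 1000.0


def time_to_threshold(
    cem43_history: np.ndarray,
    threshold: float = LESION_THRESHOLD_CEM43,
) -> np.ndarray:
    """First frame index at which the cumulative dose reaches the
    threshold; NaN for voxels that never reach it."""
    history = np.asarray(cem43_history, dtype=float)
    reached = history >= threshold
    idx = np.argmax(reached, axis=0).astype(float)
    idx[~reached.any(axis=0)] = np.nan
    return idx


def time_to_threshold_difference(
    time_a: np.ndarray, time_b: np.ndarray
) -> np.ndarray:
    """Per-voxel ``time_a - time_b``; NaN where either is undefined."""
    return np.asarray(time_a, dtype=float) - np.asarray(time_b, dtype=float)


def build_dose_map(
    cem43_history: np.ndarray,
    threshold: float = LESION_THRESHOLD_CEM43,
) -> DoseMap:
    """Final-frame :class:`DoseMap` from a cumulative dose history."""
    final = np.asarray(cem43_history[-1], dtype=float)
    return DoseMap(
        cem43=final,
        lesion_mask=final >= threshold,
        time_to_threshold=time_to_threshold(cem43_history, threshold),
        threshold=threshold,
    )


__all__.append("build_dose_map")
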