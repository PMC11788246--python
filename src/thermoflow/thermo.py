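"""PRF-shift thermometry: phase-difference to temperature conversion,
temporal unwrapping, drift correction, and causal low-pass filtering.

The water proton resonance frequency decreases linearly with temperature
(PRF coefficient sigma ≈ −0.0094 ppm/°C), so a temperature change dT adds

    dphi = 2*pi * gamma_Hz * sigma * TE * B0 * dT

radians to a gradient-echo phase image (gamma in Hz/T, TE in s, B0 in T).
Note the 2*pi: with phase measured in radians and gamma in Hz/T it is
dimensionally required, and it is included here throughout.  With the
defaults (TE = 18 ms, B0 = 1.5 T) one radian corresponds to about
−14.7 °C, so heating beyond ~46 °C wraps the phase difference and must be
recovered by temporal unwrapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "ThermometryParams",
    "TemperatureSeries",
    "phase_to_temperature",
    "temporal_unwrap",
    "drift_correct",
    "lowpass_filter",
]


@dataclass
class ThermometryParams:
    """Physical constants of the PRF temperature calculation.

    gamma : gyromagnetic ratio in MHz/T (42.58 for protons)
    sigma : PRF temperature coefficient in ppm/°C (−0.0094, negative:
        heating lowers the resonance frequency)
    te : echo time in seconds
    b0 : static field strength in tesla
    baseline_temp : body temperature at acquisition start, °C
    """

    gamma: float = 42.58
    sigma: float = -0.0094
    te: float = 0.018
    b0: float = 1.5
    baseline_temp: float = 37.0

    def __post_init__(self) -> None:
        if self.te <= 0:
            raise ValueError("te must be > 0")
        if self.b0 <= 0:
            raise ValueError("b0 must be > 0")
        if self.sigma >= 0:
            raise ValueError("sigma must be negative (PRF shifts down with heating)")

    @property
    def rad_per_degree(self) -> float:
        """Phase change per °C, in radians (negative)."""
        gamma_hz = self.gamma * 1e6
        sigma_frac = self.sigma * 1e-6
        return 2.0 * np.pi * gamma_hz * sigma_frac * self.te * self.b0

    @property
    def degrees_per_radian(self) -> float:
        return 1.0 / self.rad_per_degree


@dataclass
class TemperatureSeries:
    """Per-voxel temperature-change time courses with validity flags."""

    delta_t: np.ndarray  # (n_frames, z, r, c) °C
    valid_mask: np.ndarray  # same shape, bool
    params: ThermometryParams

    def __post_init__(self) -> None:
        self.delta_t = np.asarray(self.delta_t, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.delta_t.shape != self.valid_mask.shape:
            raise ValueError("delta_t and valid_mask shapes differ")
        if not np.all(np.isfinite(self.delta_t[self.valid_mask])):
            raise ValueError("delta_t must be finite wherever valid")

    @property
    def n_frames(self) -> int:
        return self.delta_t.shape[0]


def phase_to_temperature(
    phase_t: np.ndarray,
    phase_ref: np.ndarray,
    params: ThermometryParams | None = None,
) -> np.ndarray:
    """Temperature change from a phase difference.

    The difference ``phase_t - phase_ref`` is wrapped to (−pi, pi] before
    scaling, so single-frame changes beyond the wrap limit need
    :func:`temporal_unwrap` upstream.
    """
    params = params or ThermometryParams()
    dphi = np.angle(np.exp(1j * (np.asarray(phase_t) - np.asarray(phase_ref))))
    return dphi / params.rad_per_degree


def temporal_unwrap(delta_phase: np.ndarray, axis: int = 0) -> np.ndarray:
    """Add ±2·pi increments so consecutive samples never jump by more
    than pi along ``axis`` (time).  Best effort: assumes true
    frame-to-frame phase change stays below pi."""
    return np.unwrap(np.asarray(delta_phase, dtype=float), axis=axis)


def drift_correct(
    delta_t: np.ndarray,
    body_mask: np.ndarray | None = None,
    exclusion_threshold: float = 3.0,
    min_voxels: int = 50,
) -> np.ndarray:
    """Remove slowly varying spatial phase drift from a temperature stack.

    Per frame and per slice, a first-order 2D polynomial (offset + row and
    column ramps) is fitted over unheated in-body voxels and subtracted
    everywhere.  A voxel is excluded from the fit once its |dT| exceeded
    ``exclusion_threshold`` °C at any earlier frame, so genuine heating is
    never regressed away.  Frames/slices with fewer than ``min_voxels``
    usable voxels are left uncorrected with a warning.
    """
    delta_t = np.asarray(delta_t, dtype=float)
    n_frames, n_slices, nr, nc = delta_t.shape
    if body_mask is None:
        body_mask = np.ones((n_slices, nr, nc), dtype=bool)
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    # center coordinates for a well-conditioned fit
    rn = (rows - nr / 2.0) / nr
    cn = (cols - nc / 2.0) / nc
    design_full = np.column_stack(
        [np.ones(nr * nc), rn.ravel(), cn.ravel()]
    )
    corrected = delta_t.copy()
    ever_heated = np.zeros((n_slices, nr, nc), dtype=bool)
    for t in range(n_frames):
        for z in range(n_slices):
            fit_mask = body_mask[z] & ~ever_heated[z] & np.isfinite(delta_t[t, z])
            n_fit = int(fit_mask.sum())
            if n_fit < min_voxels:
                warnings.warn(
                    f"frame {t}, slice {z}: only {n_fit} unheated voxels; "
                    "skipping drift correction",
                    RuntimeWarning,
                    stacklevel=2,
                )
                continue
            design = design_full[fit_mask.ravel()]
            beta, *_ = np.linalg.lstsq(
                design, delta_t[t, z][fit_mask], rcond=None
            )
            plane = (design_full @ beta).reshape(nr, nc)
            corrected[t, z] = delta_t[t, z] - plane
        # flag heated voxels from the corrected estimate, so a global
        # drift never masquerades as heating and starves later fits
        ever_heated |= np.abs(corrected[t]) > exclusion_threshold
    return corrected


def lowpass_filter(
    delta_t: np.ndarray,
    frame_interval: float,
    cutoff: float = 0.14,
) -> np.ndarray:
    """Causal first-order Butterworth low-pass along the time axis.

    ``frame_interval`` is the (mean) sampling interval in seconds; the
    default 0.14 Hz cutoff suppresses residual respiratory fluctuation
    while passing the slow heating dynamics.  The filter state is
    initialized at the first sample so a constant input passes unchanged.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be > 0")
    fs = 1.0 / frame_interval
    if cutoff >= fs / 2.0:
        raise ValueError(
            f"cutoff {cutoff} Hz is not below the Nyquist frequency {fs / 2} Hz"
        )
    b, a = signal.butter(1, cutoff, fs=fs)
    x = np.asarray(delta_t, dtype=float)
    zi = signal.lfilter_zi(b, a)
    first = x[:1]
    zi_full = zi.reshape((-1,) + (1,) * (x.ndim - 1)) * first
    y, _ = signal.lfilter(b, a, x, axis=0, zi=zi_full)
    return y
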