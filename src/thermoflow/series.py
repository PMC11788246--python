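"""Core container for dynamic MR magnitude/phase series.

A dynamic thermometry acquisition is a time-ordered sequence of multi-slice
stacks: one magnitude stack and one phase stack per frame, with per-frame
timestamps and a fixed voxel geometry.  Arrays are indexed
``(frame, slice, row, col)``; displacements elsewhere in the package use
``u`` for column shifts and ``v`` for row shifts, both in voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DynamicSeries", "wrap_phase"]


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap phase values into ``[-pi, pi)``.

    Idempotent: wrapping twice equals wrapping once.
    """
    phase = np.asarray(phase, dtype=float)
    return np.mod(phase + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class DynamicSeries:
    """Time-ordered multi-slice magnitude + phase stacks.

    Parameters
    ----------
    magnitude : ndarray, shape (n_frames, n_slices, n_rows, n_cols)
        Magnitude images, arbitrary units, non-negative.
    phase : ndarray, same shape
        Phase images in radians, wrapped to ``[-pi, pi)``.
    timestamps : ndarray, shape (n_frames,)
        Acquisition time of each frame in seconds, strictly increasing.
    voxel_spacing : tuple (dx, dy, dz)
        In-plane column / row spacing and slice thickness, in mm.
    frame_interval : float
        Nominal seconds between frames (mean interval for gated series).
    """

    magnitude: np.ndarray
    phase: np.ndarray
    timestamps: np.ndarray
    voxel_spacing: tuple[float, float, float] = (2.5, 2.5, 3.0)
    frame_interval: float = field(default=0.0)

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.magnitude.ndim != 4:
            raise ValueError(
                "magnitude must be 4D (n_frames, n_slices, n_rows, n_cols); "
                f"got ndim={self.magnitude.ndim}"
            )
        if self.magnitude.shape != self.phase.shape:
            raise ValueError(
                f"magnitude shape {self.magnitude.shape} != phase shape "
                f"{self.phase.shape}"
            )
        if self.timestamps.shape != (self.n_frames,):
            raise ValueError(
                f"timestamps must have shape ({self.n_frames},); "
                f"got {self.timestamps.shape}"
            )
        if self.n_frames > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude values must be >= 0")
        self.phase = wrap_phase(self.phase)
        if self.frame_interval <= 0:
            if self.n_frames > 1:
                self.frame_interval = float(np.mean(np.diff(self.timestamps)))
            else:
                self.frame_interval = 1.0

    @property
    def n_frames(self) -> int:
        return self.magnitude.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """(n_slices, n_rows, n_cols) of every frame."""
        return self.magnitude.shape[1:]

    def frame(self, index: int) -> tuple[np.ndarray, np.ndarray]:
        """Return the (magnitude, phase) stacks of one frame."""
        return self.magnitude[index], self.phase[index]

    def complex_frame(self, index: int) -> np.ndarray:
        """Complex-valued image ``M * exp(i*phi)`` of one frame."""
        return self.magnitude[index] * np.exp(1j * self.phase[index])
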