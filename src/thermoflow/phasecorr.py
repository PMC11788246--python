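"""Motion-parameterized background phase for respiratory susceptibility
correction.

Breathing displaces abdominal organs through a spatially varying magnetic
field, so the background phase of each voxel varies with the motion state
even after perfect geometric registration.  Left uncorrected, this phase
is misread as temperature by the PRF calculation.  The model here is
first-order: per voxel, the registered (temporally unwrapped) phase is an
affine function of a small vector of motion descriptors — in this package
the coefficients of the flow on the learned eigen-motion basis.  The
model is fitted by ordinary least squares during the preparative learning
phase and frozen afterwards; during intervention the predicted background
phase is subtracted before temperature conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SusceptibilityModel", "fit_susceptibility_model", "predict_background_phase"]


@dataclass
class SusceptibilityModel:
    """Per-voxel baseline phase plus one coefficient map per descriptor."""

    baseline_phase: np.ndarray  # (z, r, c) radians
    coefficient_maps: np.ndarray  # (k, z, r, c) radians per descriptor unit

    def __post_init__(self) -> None:
        self.baseline_phase = np.asarray(self.baseline_phase, dtype=float)
        self.coefficient_maps = np.asarray(self.coefficient_maps, dtype=float)
        if self.coefficient_maps.ndim != self.baseline_phase.ndim + 1:
            raise ValueError(
                "coefficient_maps must stack one map per descriptor over the "
                "baseline grid"
            )
        if self.coefficient_maps.shape[1:] != self.baseline_phase.shape:
            raise ValueError(
                f"coefficient map grid {self.coefficient_maps.shape[1:]} != "
                f"baseline grid {self.baseline_phase.shape}"
            )

    @property
    def descriptor_count(self) -> int:
        return self.coefficient_maps.shape[0]


def fit_susceptibility_model(
    registered_phases: np.ndarray | list[np.ndarray],
    descriptors: np.ndarray | list[np.ndarray],
) -> SusceptibilityModel:
    """Fit phase = baseline + descriptors @ coefficient_maps per voxel.

    Parameters
    ----------
    registered_phases : (n_frames, z, r, c)
        Learning-phase stacks registered to the reference position and
        temporally unwrapped (wrapped phase breaks the linearity).
    descriptors : (n_frames, k)
        One motion-descriptor vector per learning frame.

    Raises
    ------
    ValueError
        If the system is underdetermined (fewer frames than k + 1).
    """
    phases = np.stack([np.asarray(p, dtype=float) for p in registered_phases])
    desc = np.atleast_2d(np.asarray(descriptors, dtype=float))
    if desc.shape[0] != phases.shape[0]:
        raise ValueError(
            f"{phases.shape[0]} phase frames but {desc.shape[0]} descriptor vectors"
        )
    n, k = desc.shape
    if n < k + 1:
        raise ValueError(
            f"underdetermined fit: {n} learning frames for {k} descriptors "
            f"(need >= {k + 1})"
        )
    grid = phases.shape[1:]
    design = np.column_stack([np.ones(n), desc])  # (n, k+1)
    beta, *_ = np.linalg.lstsq(design, phases.reshape(n, -1), rcond=None)
    baseline = beta[0].reshape(grid)
    coeff_maps = beta[1:].reshape(k, *grid)
    return SusceptibilityModel(baseline_phase=baseline, coefficient_maps=coeff_maps)


def predict_background_phase(
    model: SusceptibilityModel, descriptors: np.ndarray
) -> np.ndarray:
    """Background phase for one motion state:
    ``phi_ref = baseline + sum_k c_k * coefficient_map_k``."""
    descriptors = np.asarray(descriptors, dtype=float).ravel()
    if descriptors.shape[0] != model.descriptor_count:
        raise ValueError(
            f"descriptor length {descriptors.shape[0]} != model descriptor "
            f"count {model.descriptor_count}"
        )
    return model.baseline_phase + np.tensordot(
        descriptors, model.coefficient_maps, axes=(0, 0)
    )
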