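"""Synthetic dynamic-series generator with known ground truth.

The phantom emulates the conditions of MR-guided liver microwave ablation
monitored by multi-slice EPI thermometry:

* a smooth liver-like template with vessel-like dark structures inside a
  soft-edged elliptical body;
* periodic respiratory displacement, dominantly head–foot (rows), with a
  Gaussian-windowed spatial envelope that makes the field non-rigid and
  an asymmetric temporal profile (long end-exhale plateau);
* either gated sampling (frames taken near end-exhale with a residual
  jitter of a fraction of a voxel) or fixed-frequency sampling that
  strides through the breathing cycle (e.g. every 2 s against a ~4.7 s
  respiratory period);
* a Gaussian heating hotspot obeying the PRF phase relation, accompanied
  by a time-locked multiplicative magnitude signal drop (up to ~80%) —
  the intensity change that derails brightness-constancy registration;
* motion-coupled background phase (susceptibility term linear in the
  local displacement), slow global phase drift, and additive complex
  Gaussian noise (hence Rician magnitude statistics).

Every random draw goes through one seeded generator, so equal seeds give
bit-identical series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .dose import LESION_THRESHOLD_CEM43, accumulate_cem43
from .flow import FlowField
from .series import DynamicSeries, wrap_phase
from .thermo import ThermometryParams

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "generate_series",
    "preset_config",
    "respiratory_profile",
    "PROFILE_CYCLE_MEAN",
]


def respiratory_profile(tau: np.ndarray | float) -> np.ndarray | float:
    """Normalized breathing displacement profile over cycle phase ``tau``
    (radians).  ``((1 - cos tau)/2)**2``: zero at end-exhale, 1 at peak
    inhale, asymmetric in the sense that most of the cycle is spent near
    end-exhale, as in quiet ventilated breathing."""
    return ((1.0 - np.cos(tau)) / 2.0) ** 2


#: Analytic mean of :func:`respiratory_profile` over one full cycle.
PROFILE_CYCLE_MEAN = 3.0 / 8.0


@dataclass
class PhantomConfig:
    """Phantom acquisition/heating regime.

    Units: spatial quantities in voxels, times in seconds, temperatures
    in °C, phases in radians.  ``susceptibility_gain`` is the background
    phase added per voxel of local displacement; ``noise_sd`` the complex
    noise standard deviation as a fraction of mean body magnitude;
    ``drift_rate`` the global phase drift per frame.
    """

    grid: tuple[int, int, int] = (1, 96, 96)
    n_frames: int = 60
    frame_interval: float = 2.0
    mode: str = "fixed_frequency"  # or "gated"
    respiratory_period: float = 4.7
    displacement_amplitude: float = 4.0
    gating_jitter: float = 0.3
    hotspot_center: tuple[int, int, int] | None = None
    hotspot_sigma: float = 3.0
    peak_delta_t: float = 50.0
    heating_window: tuple[int, int] | None = None
    max_signal_drop: float = 0.5
    susceptibility_gain: float = 0.1
    noise_sd: float = 0.02
    drift_rate: float = 0.005
    voxel_spacing: tuple[float, float, float] = (2.5, 2.5, 3.0)
    thermometry: ThermometryParams = field(default_factory=ThermometryParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_signal_drop <= 1.0:
            raise ValueError("max_signal_drop must lie in [0, 1]")
        if self.displacement_amplitude < 0:
            raise ValueError("displacement_amplitude must be >= 0")
        if self.n_frames < 20:
            raise ValueError(
                "n_frames must be >= 20 (15 learning frames plus intervention)"
            )
        if self.mode not in {"gated", "fixed_frequency"}:
            raise ValueError("mode must be 'gated' or 'fixed_frequency'")
        nz, nr, nc = self.grid
        if self.hotspot_center is None:
            self.hotspot_center = (nz // 2, nr // 2, nc // 2)
        if self.heating_window is None:
            self.heating_window = (20, max(21, self.n_frames - 10))
        f0, f1 = self.heating_window
        if not (0 <= f0 < f1 <= self.n_frames):
            raise ValueError(
                f"heating_window {self.heating_window} outside [0, {self.n_frames})"
            )


@dataclass
class GroundTruth:
    """Exact motion and temperature used to synthesize a series.

    ``true_flow[t]`` is the registration flow from frame ``t`` to the
    undisplaced template grid, in the same pull-back convention the flow
    estimators use; ``true_delta_t`` is the temperature change at the
    template grid.  Helper methods re-express both relative to any frame
    chosen as the reference position.
    """

    true_flow: list[FlowField]
    true_delta_t: np.ndarray  # (n_frames, z, r, c)
    true_lesion_mask: np.ndarray  # (z, r, c)
    amplitudes: np.ndarray  # per-frame displacement amplitude a(t), voxels
    heating_profile: np.ndarray  # per-frame h(t) in [0, 1]
    config: PhantomConfig

    def _envelope(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return _motion_envelope(self.config, rows, cols)

    def _hotspot(self, rows: np.ndarray, cols: np.ndarray, z: int) -> np.ndarray:
        return _hotspot_profile(self.config, z, rows, cols)

    def flow_to_reference(self, t: int, ref_index: int) -> FlowField:
        """True registration flow from frame ``t`` to the grid of frame
        ``ref_index`` (both solved by fixed-point inversion of the
        analytic forward displacement)."""
        cfg = self.config
        nz, nr, nc = cfg.grid
        rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        # ref-grid voxel x carries the material point at template coord
        # x - D_ref(x)
        row_template = rows - self.amplitudes[ref_index] * _motion_envelope(
            cfg, rows, cols
        )
        # position of that material point in frame t: y = x_b + a_t E(y)
        y = row_template.copy()
        for _ in range(8):
            y = row_template + self.amplitudes[t] * _motion_envelope(cfg, y, cols)
        v = y - rows
        field3d = np.broadcast_to(v, (nz, nr, nc)).copy()
        return FlowField(np.zeros((nz, nr, nc)), field3d)

    def delta_t_at_reference(self, ref_index: int) -> np.ndarray:
        """True temperature series expressed at the grid of frame
        ``ref_index`` (the frame workflows register to)."""
        cfg = self.config
        nz, nr, nc = cfg.grid
        rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        a_ref = self.amplitudes[ref_index]
        row_b = rows - a_ref * _motion_envelope(cfg, rows, cols)
        out = np.zeros((cfg.n_frames, nz, nr, nc))
        for z in range(nz):
            spot = _hotspot_profile(cfg, z, row_b, cols)
            for t in range(cfg.n_frames):
                out[t, z] = cfg.peak_delta_t * self.heating_profile[t] * spot
        return out


# ---------------------------------------------------------------------------
# analytic building blocks
# ---------------------------------------------------------------------------

def _motion_envelope(cfg: PhantomConfig, rows, cols) -> np.ndarray:
    """Smooth spatial amplitude scaling in [0.5, 1], Gaussian-windowed;
    non-rigid but slowly varying, peaking off-center like the diaphragm
    side of the liver."""
    _, nr, nc = cfg.grid
    er, ec = 0.40 * nr, 0.50 * nc
    w = 0.45 * min(nr, nc)
    return 0.5 + 0.5 * np.exp(-(((rows - er) ** 2) + (cols - ec) ** 2) / (2 * w**2))


def _hotspot_profile(cfg: PhantomConfig, z: int, rows, cols) -> np.ndarray:
    """Normalized Gaussian hotspot footprint at slice ``z`` (template
    coordinates); through-slice falloff is twice as fast as in-plane
    since slices are thicker than in-plane voxels."""
    z0, r0, c0 = cfg.hotspot_center  # type: ignore[misc]
    rho2 = (rows - r0) ** 2 + (cols - c0) ** 2 + (2.0 * (z - z0)) ** 2
    return np.exp(-rho2 / (2.0 * cfg.hotspot_sigma**2))


def _solve_pullback(cfg: PhantomConfig, amplitude: float, rows, cols) -> np.ndarray:
    """Fixed point g = a * E(row + g, col): the registration flow (row
    component) from the displaced frame back to the template grid."""
    g = np.zeros_like(rows, dtype=float)
    for _ in range(8):
        g = amplitude * _motion_envelope(cfg, rows + g, cols)
    return g


def _heating_profile(cfg: PhantomConfig) -> np.ndarray:
    """Per-frame heating fraction: saturating exponential rise over the
    heating window, exponential cool-down after it."""
    f0, f1 = cfg.heating_window  # type: ignore[misc]
    t = np.arange(cfg.n_frames, dtype=float)
    h = np.zeros(cfg.n_frames)
    rise = (1.0 - np.exp(-3.0 * (t - f0) / max(f1 - f0, 1))) / (1.0 - np.exp(-3.0))
    in_window = (t >= f0) & (t < f1)
    h[in_window] = rise[in_window]
    after = t >= f1
    tau_cool = max((f1 - f0) / 2.0, 1.0)
    h[after] = h[f1 - 1] if f1 > f0 else 0.0
    h[after] = (rise[f1 - 1] if f1 - 1 >= f0 else 0.0) * np.exp(
        -(t[after] - (f1 - 1)) / tau_cool
    )
    return np.clip(h, 0.0, None)


def _build_template(cfg: PhantomConfig, rng: np.random.Generator):
    """Liver-like template magnitude and smooth baseline phase."""
    _, nr, nc = cfg.grid
    base = ndimage.gaussian_filter(rng.normal(size=(nr, nc)), sigma=6.0)
    base = 0.6 + 0.4 * (base - base.min()) / max(np.ptp(base), 1e-12)
    # vessel-like dark elongated structures
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    for _ in range(4):
        r0, c0 = rng.uniform(0.25, 0.75, 2) * (nr, nc)
        theta = rng.uniform(0, np.pi)
        d = (rows - r0) * np.sin(theta) - (cols - c0) * np.cos(theta)
        base *= 1.0 - 0.45 * np.exp(-(d**2) / (2 * 1.5**2))
    # soft-edged elliptical body
    e = ((rows - nr / 2) / (0.44 * nr)) ** 2 + ((cols - nc / 2) / (0.44 * nc)) ** 2
    body = 1.0 / (1.0 + np.exp((e - 1.0) / 0.02))
    template = base * body + 0.02
    phase0 = ndimage.gaussian_filter(rng.normal(size=(nr, nc)), sigma=10.0)
    phase0 *= 0.5 / max(phase0.std(), 1e-12)
    return template, phase0, body > 0.5


def _sample_amplitudes(cfg: PhantomConfig, rng: np.random.Generator):
    """Per-frame timestamps and displacement amplitudes a(t)."""
    n = cfg.n_frames
    if cfg.mode == "gated":
        intervals = cfg.frame_interval * (1.0 + 0.05 * rng.standard_normal(n))
        intervals = np.clip(intervals, 0.5 * cfg.frame_interval, None)
        timestamps = np.concatenate([[0.0], np.cumsum(intervals[:-1])])
        # sampled near end-exhale; residual position error = gating jitter
        amplitudes = np.abs(rng.normal(0.0, cfg.gating_jitter, size=n))
    else:
        timestamps = np.arange(n) * cfg.frame_interval
        tau = 2.0 * np.pi * timestamps / cfg.respiratory_period
        amplitudes = cfg.displacement_amplitude * np.asarray(
            respiratory_profile(tau)
        )
    return timestamps, amplitudes


def generate_series(cfg: PhantomConfig) -> tuple[DynamicSeries, GroundTruth]:
    """Synthesize a dynamic magnitude/phase series plus its ground truth.

    Per frame the template is displaced by the respiratory field, the
    hotspot adds PRF phase and multiplies the magnitude by the
    signal-drop well, the susceptibility term couples phase to local
    displacement, and complex Gaussian noise plus drift are applied.
    """
    rng = np.random.default_rng(cfg.seed)
    nz, nr, nc = cfg.grid
    template2d, phase0, body2d = _build_template(cfg, rng)
    timestamps, amplitudes = _sample_amplitudes(cfg, rng)
    h = _heating_profile(cfg)
    prf_rad_per_c = cfg.thermometry.rad_per_degree

    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    body_mean = float(template2d[body2d].mean())
    noise_sigma = cfg.noise_sd * body_mean

    slice_gain = 1.0 - 0.03 * np.abs(
        np.arange(nz) - cfg.hotspot_center[0]  # type: ignore[index]
    )

    magnitude = np.empty((cfg.n_frames, nz, nr, nc))
    phase = np.empty((cfg.n_frames, nz, nr, nc))
    true_delta_t = np.zeros((cfg.n_frames, nz, nr, nc))
    true_flow: list[FlowField] = []

    for t in range(cfg.n_frames):
        a = amplitudes[t]
        disp = a * _motion_envelope(cfg, rows, cols)  # forward displacement at y
        row_back = rows - disp
        for z in range(nz):
            mag_t = ndimage.map_coordinates(
                template2d * slice_gain[z], [row_back, cols],
                order=3, mode="nearest",
            )
            phi_b = ndimage.map_coordinates(
                phase0, [row_back, cols], order=3, mode="nearest"
            )
            spot = _hotspot_profile(cfg, z, row_back, cols)
            dt_field = cfg.peak_delta_t * h[t] * spot
            drop = cfg.max_signal_drop * h[t] * spot
            mag = mag_t * (1.0 - drop)
            phi = (
                phi_b
                + cfg.susceptibility_gain * disp
                + prf_rad_per_c * dt_field
                + cfg.drift_rate * t
            )
            cplx = mag * np.exp(1j * phi)
            if noise_sigma > 0:
                cplx = cplx + noise_sigma * (
                    rng.standard_normal((nr, nc))
                    + 1j * rng.standard_normal((nr, nc))
                )
            magnitude[t, z] = np.abs(cplx)
            phase[t, z] = np.angle(cplx)
            spot_ref = _hotspot_profile(cfg, z, rows, cols)
            true_delta_t[t, z] = cfg.peak_delta_t * h[t] * spot_ref
        g = _solve_pullback(cfg, a, rows, cols)
        true_flow.append(
            FlowField(
                np.zeros((nz, nr, nc)),
                np.broadcast_to(g, (nz, nr, nc)).copy(),
            )
        )

    series = DynamicSeries(
        magnitude=magnitude,
        phase=wrap_phase(phase),
        timestamps=timestamps,
        voxel_spacing=cfg.voxel_spacing,
        frame_interval=cfg.frame_interval,
    )
    dt_frames = np.concatenate([[cfg.frame_interval], np.diff(timestamps)])
    cem = accumulate_cem43(
        true_delta_t, dt_frames, baseline_temp=cfg.thermometry.baseline_temp
    )
    truth = GroundTruth(
        true_flow=true_flow,
        true_delta_t=true_delta_t,
        true_lesion_mask=cem[-1] >= LESION_THRESHOLD_CEM43,
        amplitudes=amplitudes,
        heating_profile=h,
        config=cfg,
    )
    return series, truth


def preset_config(name: str, **overrides) -> PhantomConfig:
    """Named acquisition regimes mirroring the clinical protocols.

    ``gated_paper``: respiratory-gated, ~4 s between frames, 13 slices.
    ``fixed_frequency_paper``: continuous 0.5 Hz sampling (2.0 s frame
    interval), 13 slices, ~50 °C peak heating with 50% signal drop.
    Keyword overrides replace individual fields.
    """
    presets = {
        "gated_paper": dict(
            grid=(13, 128, 128),
            n_frames=180,
            frame_interval=4.0,
            mode="gated",
            respiratory_period=4.7,
            displacement_amplitude=4.5,
            gating_jitter=0.3,
            peak_delta_t=50.0,
            heating_window=(20, 150),
            max_signal_drop=0.5,
            voxel_spacing=(2.5, 2.5, 3.0),
        ),
        "fixed_frequency_paper": dict(
            grid=(13, 128, 128),
            n_frames=350,
            frame_interval=2.0,
            mode="fixed_frequency",
            respiratory_period=4.7,
            displacement_amplitude=4.5,
            peak_delta_t=50.0,
            heating_window=(20, 290),
            max_signal_drop=0.5,
            voxel_spacing=(2.5, 2.5, 3.0),
        ),
    }
    if name not in presets:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    params = dict(presets[name])
    params.update(overrides)
    return PhantomConfig(**params)
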