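"""Deformable 2D registration: Horn–Schunck optical flow and its
PCA-constrained variant.

The conventional estimator solves the classic Horn–Schunck variational
problem slice by slice — a brightness-constancy data term plus an
``alpha**2``-weighted smoothness term — coarse-to-fine over an image
pyramid with intermediate warping.  Because it trusts brightness
constancy everywhere, a local intensity change (e.g. the signal drop
around a heated ablation zone) is misread as motion.

The PCA-constrained estimator instead searches only the low-dimensional
subspace of motion fields spanned by eigen-flows learned from a
preparative breathing-only period.  A localized intensity change cannot
be expressed in that subspace, so the motion estimate stays clean during
heating — this is the property the whole pipeline relies on.

Conventions: flow ``F = (u, v)`` is stored at the reference grid in the
pull-back sense, ``moving(x + F(x)) ≈ reference(x)``; ``u`` shifts
columns, ``v`` shifts rows, both in voxels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FlowField",
    "FlowBasis",
    "HSParams",
    "PCAFlowParams",
    "estimate_flow_hs",
    "estimate_flow_pca",
    "warp_image",
    "warp_stack",
    "select_reference_frame",
    "build_flow_basis",
]


@dataclass
class FlowField:
    """Per-voxel in-plane displacement, one 2D field per slice.

    ``u``: column displacement (voxels), ``v``: row displacement (voxels);
    both shaped (n_slices, n_rows, n_cols).
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.shape != self.v.shape:
            raise ValueError(f"u shape {self.u.shape} != v shape {self.v.shape}")
        if self.u.ndim != 3:
            raise ValueError("flow components must be 3D (n_slices, n_rows, n_cols)")

    @classmethod
    def zeros(cls, grid_shape: tuple[int, int, int]) -> "FlowField":
        return cls(np.zeros(grid_shape), np.zeros(grid_shape))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        """Euclidean norm of the displacement per voxel (voxels)."""
        return np.hypot(self.u, self.v)

    def flatten(self) -> np.ndarray:
        """Concatenate (u, v) into one vector; inverse of `from_vector`."""
        return np.concatenate([self.u.ravel(), self.v.ravel()])

    @classmethod
    def from_vector(cls, vec: np.ndarray, grid_shape: tuple[int, int, int]) -> "FlowField":
        n = int(np.prod(grid_shape))
        return cls(vec[:n].reshape(grid_shape), vec[n:].reshape(grid_shape))

    def __add__(self, other: "FlowField") -> "FlowField":
        return FlowField(self.u + other.u, self.v + other.v)

    def __mul__(self, scalar: float) -> "FlowField":
        return FlowField(self.u * scalar, self.v * scalar)

    __rmul__ = __mul__


@dataclass
class HSParams:
    """Horn–Schunck solver parameters.

    ``alpha`` is the smoothness weight on unit-normalized intensities;
    three pyramid levels (downscale x2) with intermediate re-warping and
    up to ``n_iterations`` Jacobi sweeps per warp, stopping early when the
    mean flow update drops below ``tolerance`` voxels.
    """

    alpha: float = 0.1
    n_iterations: int = 100
    pyramid_levels: int = 3
    tolerance: float = 1e-3
    n_warps: int = 3
    #: Gaussian presmoothing of both images before differentiation, in
    #: voxels; standard optical-flow practice to keep image noise out of
    #: the brightness-constancy derivatives.
    presmooth_sigma: float = 1.0


@dataclass
class PCAFlowParams:
    """Gauss–Newton settings for the subspace coefficient fit."""

    n_gauss_newton: int = 10
    tolerance: float = 1e-4


# Horn–Schunck neighbourhood average weights.
_HS_KERNEL = np.array(
    [[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0.0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]]
)


def _normalize_pair(moving: np.ndarray, reference: np.ndarray):
    scale = max(float(np.max(np.abs(moving))), float(np.max(np.abs(reference))))
    if scale == 0:
        return moving, reference, 0.0
    return moving / scale, reference / scale, scale


def _warp2d(image: np.ndarray, u: np.ndarray, v: np.ndarray, order: int = 1):
    """Sample ``image`` at (row + v, col + u); returns (warped, inbounds)."""
    nr, nc = image.shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    rr = rows + v
    cc = cols + u
    warped = ndimage.map_coordinates(image, [rr, cc], order=order, mode="nearest")
    valid = (rr >= 0) & (rr <= nr - 1) & (cc >= 0) & (cc <= nc - 1)
    return warped, valid


def _hs_single_level(moving, reference, u, v, params: HSParams):
    """Solve linearized H&S at one pyramid level, warm-started at (u, v)."""
    a2 = params.alpha**2
    for _ in range(params.n_warps):
        warped, _ = _warp2d(moving, u, v)
        # derivatives of the warped moving image; averaging with the
        # reference stabilizes the linearization
        gy, gx = np.gradient(0.5 * (warped + reference))
        it = warped - reference
        # linearize about the warp used for `it`
        u0, v0 = u.copy(), v.copy()
        t_term = it - gx * u0 - gy * v0
        den = a2 + gx**2 + gy**2
        for _ in range(params.n_iterations):
            ubar = ndimage.convolve(u, _HS_KERNEL, mode="nearest")
            vbar = ndimage.convolve(v, _HS_KERNEL, mode="nearest")
            num = gx * ubar + gy * vbar + t_term
            u_new = ubar - gx * num / den
            v_new = vbar - gy * num / den
            delta = np.mean(np.abs(u_new - u) + np.abs(v_new - v))
            u, v = u_new, v_new
            if delta < params.tolerance:
                break
    return u, v


def _pyramid(image: np.ndarray, levels: int):
    pyr = [image]
    for _ in range(levels - 1):
        smoothed = ndimage.gaussian_filter(pyr[-1], sigma=1.0)
        pyr.append(ndimage.zoom(smoothed, 0.5, order=1, grid_mode=True, mode="nearest"))
    return pyr[::-1]  # coarse to fine


def _hs_slice(moving: np.ndarray, reference: np.ndarray, params: HSParams):
    if params.presmooth_sigma > 0:
        moving = ndimage.gaussian_filter(moving, params.presmooth_sigma)
        reference = ndimage.gaussian_filter(reference, params.presmooth_sigma)
    levels = max(1, min(params.pyramid_levels,
                        int(np.log2(min(moving.shape))) - 3))
    pyr_mov = _pyramid(moving, levels)
    pyr_ref = _pyramid(reference, levels)
    u = np.zeros_like(pyr_mov[0])
    v = np.zeros_like(pyr_mov[0])
    for lev, (m, r) in enumerate(zip(pyr_mov, pyr_ref)):
        if lev > 0:
            zoom = np.array(m.shape) / np.array(u.shape)
            u = ndimage.zoom(u, zoom, order=1, mode="nearest") * zoom[1]
            v = ndimage.zoom(v, zoom, order=1, mode="nearest") * zoom[0]
        u, v = _hs_single_level(m, r, u, v, params)
    return u, v


def estimate_flow_hs(
    moving: np.ndarray,
    reference: np.ndarray,
    params: HSParams | None = None,
) -> FlowField:
    """Conventional Horn–Schunck optical flow, slice by slice.

    Returns the flow ``F`` with ``moving(x + F(x)) ≈ reference(x)``.
    Intensities are normalized internally to a common unit scale.
    """
    params = params or HSParams()
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.shape != reference.shape:
        raise ValueError(f"shape mismatch: {moving.shape} vs {reference.shape}")
    if moving.ndim == 2:
        moving = moving[None]
        reference = reference[None]
        squeeze = True
    else:
        squeeze = False
    if not (np.all(np.isfinite(moving)) and np.all(np.isfinite(reference))):
        raise ValueError("non-finite values in input images")

    u = np.zeros_like(moving)
    v = np.zeros_like(moving)
    for z in range(moving.shape[0]):
        m, r, scale = _normalize_pair(moving[z], reference[z])
        if scale == 0 or np.ptp(m) == 0 or np.ptp(r) == 0:
            warnings.warn(
                f"slice {z}: zero-variance image, returning zero flow",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        u[z], v[z] = _hs_slice(m, r, params)
    flow = FlowField(u, v)
    if squeeze:
        return flow
    return flow


def warp_image(
    image: np.ndarray,
    flow: FlowField,
    interpolation: str = "bilinear",
) -> tuple[np.ndarray, np.ndarray]:
    """Warp an image stack by a flow field: ``out(x) = image(x + flow(x))``.

    Complex inputs are warped through their real and imaginary parts so
    that phase images interpolate correctly.  Returns ``(warped, valid)``
    where ``valid`` is False wherever the sample fell outside the grid.
    """
    if interpolation != "bilinear":
        raise ValueError("only bilinear interpolation is supported")
    image = np.asarray(image)
    arr = image[None] if image.ndim == 2 else image
    if arr.shape != flow.grid_shape:
        raise ValueError(f"image shape {arr.shape} != flow grid {flow.grid_shape}")
    warped = np.empty_like(arr)
    valid = np.empty(arr.shape, dtype=bool)
    for z in range(arr.shape[0]):
        if np.iscomplexobj(arr):
            re, val = _warp2d(arr[z].real, flow.u[z], flow.v[z])
            im, _ = _warp2d(arr[z].imag, flow.u[z], flow.v[z])
            warped[z] = re + 1j * im
        else:
            warped[z], val = _warp2d(arr[z], flow.u[z], flow.v[z])
        valid[z] = val
    if image.ndim == 2:
        return warped[0], valid[0]
    return warped, valid


def warp_stack(image: np.ndarray, flow: FlowField) -> tuple[np.ndarray, np.ndarray]:
    """Alias of :func:`warp_image` for 3D stacks."""
    return warp_image(image, flow)


def select_reference_frame(series, n_initial: int = 10) -> int:
    """Pick the reference position as the median of the first frames.

    The scalar position of each of the first ``n_initial`` frames is the
    spatial mean of its flow (vs frame 0) along the dominant motion axis;
    the frame whose position is the (lower) median is returned.  Ties go
    to the earliest frame.
    """
    if n_initial < 3:
        raise ValueError("n_initial must be >= 3")
    if series.n_frames < n_initial:
        raise ValueError(
            f"series has {series.n_frames} frames; need >= {n_initial}"
        )
    flows = [FlowField.zeros(series.grid_shape)]
    for i in range(1, n_initial):
        flows.append(estimate_flow_hs(series.magnitude[i], series.magnitude[0]))
    mean_u = np.array([np.mean(f.u) for f in flows])
    mean_v = np.array([np.mean(f.v) for f in flows])
    # dominant axis = larger spread of mean displacement
    positions = mean_v if np.ptp(mean_v) >= np.ptp(mean_u) else mean_u
    order = np.argsort(positions, kind="stable")
    median_idx = int(order[(n_initial - 1) // 2])
    # tie rule: earliest frame among positions equal to the median value
    med_val = positions[median_idx]
    ties = np.flatnonzero(positions == med_val)
    return int(ties[0])


@dataclass
class FlowBasis:
    """Mean flow + orthonormal eigen-flows from a learning period.

    ``components`` are mutually orthonormal under the flattened (u, v)
    inner product; ``explained_variance`` fractions are non-increasing.
    """

    mean_flow: FlowField
    components: list[FlowField] = field(default_factory=list)
    explained_variance: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def n_retained(self) -> int:
        return len(self.components)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.mean_flow.grid_shape

    def reconstruct(self, coefficients: np.ndarray) -> FlowField:
        """``mean_flow + sum_k a_k * component_k``."""
        coefficients = np.asarray(coefficients, dtype=float)
        if coefficients.shape != (self.n_retained,):
            raise ValueError(
                f"expected {self.n_retained} coefficients, got {coefficients.shape}"
            )
        vec = self.mean_flow.flatten().copy()
        for a, comp in zip(coefficients, self.components):
            vec += a * comp.flatten()
        return FlowField.from_vector(vec, self.grid_shape)

    def project(self, flow: FlowField) -> np.ndarray:
        """Coefficients of the mean-removed flow on each component."""
        resid = flow.flatten() - self.mean_flow.flatten()
        return np.array([resid @ c.flatten() for c in self.components])


def build_flow_basis(
    flows: list[FlowField],
    variance_threshold: float = 0.95,
    max_components: int = 5,
) -> FlowBasis:
    """PCA of mean-removed flattened (u, v) fields.

    Retains the smallest number of components whose cumulative explained
    variance reaches ``variance_threshold``, capped at ``max_components``.
    All-identical flows yield a mean-only basis with a warning.
    """
    if len(flows) < 2:
        raise ValueError("need at least 2 flows to build a basis")
    grid = flows[0].grid_shape
    if any(f.grid_shape != grid for f in flows):
        raise ValueError("all flows must share one grid shape")
    data = np.stack([f.flatten() for f in flows])  # (n, 2*voxels)
    mean_vec = data.mean(axis=0)
    centered = data - mean_vec
    total_var = float(np.sum(centered**2))
    mean_flow = FlowField.from_vector(mean_vec, grid)
    if total_var < 1e-24:
        warnings.warn(
            "all flows identical: basis has 0 components", RuntimeWarning,
            stacklevel=2,
        )
        return FlowBasis(mean_flow=mean_flow)
    # SVD of the (small n) x (large p) matrix
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    var_frac = s**2 / np.sum(s**2)
    cum = np.cumsum(var_frac)
    n_keep = int(np.searchsorted(cum, variance_threshold) + 1)
    n_keep = min(n_keep, max_components, len(s))
    components = [FlowField.from_vector(vt[k], grid) for k in range(n_keep)]
    return FlowBasis(
        mean_flow=mean_flow,
        components=components,
        explained_variance=var_frac[:n_keep],
    )


def estimate_flow_pca(
    moving: np.ndarray,
    reference: np.ndarray,
    basis: FlowBasis,
    params: PCAFlowParams | None = None,
) -> tuple[FlowField, np.ndarray]:
    """Optical flow constrained to the learned motion subspace.

    The flow is ``mean_flow + sum_k a_k component_k`` with coefficients
    solving the linearized brightness-constancy least squares in the
    k-dimensional subspace (Gauss–Newton with re-warping, spatially
    weighted by local gradient magnitude).  By construction the output
    cannot contain localized deformation outside the learned subspace.
    """
    params = params or PCAFlowParams()
    moving = np.asarray(moving, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if moving.ndim == 2:
        moving = moving[None]
        reference = reference[None]
    if moving.shape != basis.grid_shape:
        raise ValueError(
            f"image grid {moving.shape} != basis grid {basis.grid_shape}"
        )
    k = basis.n_retained
    if k == 0:
        warnings.warn(
            "empty basis: returning mean flow with zero coefficients",
            RuntimeWarning,
            stacklevel=2,
        )
        return basis.mean_flow, np.zeros(0)

    scale = max(float(np.max(np.abs(moving))), float(np.max(np.abs(reference))))
    if scale > 0:
        moving = moving / scale
        reference = reference / scale

    a = np.zeros(k)
    comp_u = np.stack([c.u for c in basis.components])  # (k, z, r, c)
    comp_v = np.stack([c.v for c in basis.components])
    for _ in range(params.n_gauss_newton):
        flow = basis.reconstruct(a)
        warped, valid = warp_image(moving, flow)
        grads = np.gradient(warped, axis=(1, 2))
        gy, gx = grads[0], grads[1]
        resid = warped - reference
        w = np.hypot(gx, gy) * valid
        # Jacobian column k at voxel i: gx*Bu_k + gy*Bv_k
        jac = gx[None] * comp_u + gy[None] * comp_v  # (k, z, r, c)
        jw = (jac * w[None]).reshape(k, -1)
        jmat = jac.reshape(k, -1)
        lhs = jw @ jmat.T
        rhs = -jw @ resid.ravel()
        try:
            delta = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
        a = a + delta
        if np.max(np.abs(delta)) < params.tolerance:
            break
    return basis.reconstruct(a), a
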