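"""Optical-flow estimators, warping, reference selection and the
eigen-flow basis."""

import numpy as np
import pytest
from scipy import ndimage

from thermoflow.flow import (
    FlowBasis,
    FlowField,
    HSParams,
    build_flow_basis,
    estimate_flow_hs,
    estimate_flow_pca,
    select_reference_frame,
    warp_image,
)
from thermoflow.series import DynamicSeries


def _const_flow(grid, u=0.0, v=0.0):
    return FlowField(np.full(grid, float(u)), np.full(grid, float(v)))


def _smooth_field(shape, seed, scale=1.0, sigma=20.0):
    rng = np.random.default_rng(seed)
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma=sigma)
    return f / max(np.max(np.abs(f)), 1e-12) * scale


class TestHornSchunck:
    def test_identity_gives_zero_flow(self, smooth_image):
        f = estimate_flow_hs(smooth_image, smooth_image)
        assert np.max(np.abs(f.u)) < 0.05
        assert np.max(np.abs(f.v)) < 0.05

    def test_recovers_unit_column_translation(self, smooth_image):
        # moving(col) = ref(col - 1), so moving(x + (1,0)) == ref(x)
        moving = np.roll(smooth_image, 1, axis=1)
        f = estimate_flow_hs(moving, smooth_image)
        interior = np.s_[0, 10:-10, 10:-10]
        assert abs(np.mean(f.u[interior]) - 1.0) < 0.2
        assert abs(np.mean(f.v[interior])) < 0.2

    def test_signal_dropout_creates_spurious_flow(self, smooth_image):
        """A heating-like intensity well with zero true motion is misread
        as motion by the brightness-constancy data term."""
        rows, cols = np.meshgrid(*map(np.arange, smooth_image.shape), indexing="ij")
        disc = np.exp(-((rows - 64) ** 2 + (cols - 64) ** 2) / (2 * 4.0**2))
        moving = smooth_image * (1.0 - 0.5 * disc)
        f = estimate_flow_hs(moving, smooth_image)
        ee = f.magnitude()[0][disc > 0.1]
        assert ee.max() > 0.5

    def test_non_finite_input_rejected(self, smooth_image):
        bad = smooth_image.copy()
        bad[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            estimate_flow_hs(bad, smooth_image)

    def test_zero_variance_image_warns_zero_flow(self):
        flat = np.ones((32, 32))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            f = estimate_flow_hs(flat, flat)
        assert np.all(f.u == 0) and np.all(f.v == 0)


class TestWarp:
    def test_zero_flow_identity(self, small_image):
        out, valid = warp_image(small_image, _const_flow((1, 64, 64)))
        assert np.allclose(out, small_image)
        assert valid.all()

    def test_integer_shift_matches_roll(self, small_image):
        out, valid = warp_image(small_image, _const_flow((1, 64, 64), u=1.0))
        # out(c) = image(c + 1)
        assert np.allclose(out[:, :-1], small_image[:, 1:])
        assert not valid[:, -1].any()

    def test_forward_backward_near_inverse(self, small_image):
        grid = (1, 64, 64)
        flow = FlowField(
            _smooth_field(grid, 1, scale=2.0), _smooth_field(grid, 2, scale=2.0)
        )
        fwd, _ = warp_image(small_image, flow)
        back, valid = warp_image(fwd, FlowField(-flow.u, -flow.v))
        interior = valid & (np.abs(flow.u[0]) < 1.5) & (np.abs(flow.v[0]) < 1.5)
        rmse = np.sqrt(np.mean((back[interior] - small_image[interior]) ** 2))
        assert rmse < 0.05 * np.ptp(small_image)

    def test_linearity(self, small_image):
        flow = FlowField(
            _smooth_field((1, 64, 64), 3, 1.5), _smooth_field((1, 64, 64), 4, 1.5)
        )
        other = small_image[::-1].copy()
        combo, _ = warp_image(2.0 * small_image + 3.0 * other, flow)
        w1, _ = warp_image(small_image, flow)
        w2, _ = warp_image(other, flow)
        assert np.allclose(combo, 2.0 * w1 + 3.0 * w2, atol=1e-10)

    def test_complex_phase_warp(self, small_image):
        """Phase warps through the complex image, never across the wrap."""
        phase = np.pi * (2 * small_image - 1) * 0.98
        cplx = np.exp(1j * phase)
        flow = _const_flow((1, 64, 64), u=0.5)
        out, _ = warp_image(cplx, flow)
        assert np.iscomplexobj(out)
        assert np.all(np.abs(out) <= 1.0 + 1e-9)

    def test_shape_mismatch_rejected(self, small_image):
        with pytest.raises(ValueError, match="shape"):
            warp_image(small_image, _const_flow((1, 32, 32)))


class TestReferenceSelection:
    def _series_with_shifts(self, image, shifts):
        frames = np.stack(
            [ndimage.shift(image, (s, 0.0), order=1, mode="nearest") for s in shifts]
        )[:, None]
        return DynamicSeries(
            magnitude=frames - frames.min() + 0.01,
            phase=np.zeros_like(frames),
            timestamps=np.arange(len(shifts), dtype=float),
        )

    def test_identical_frames_tie_returns_first(self, small_image):
        series = self._series_with_shifts(small_image, [0.0] * 10)
        assert select_reference_frame(series, 10) == 0

    def test_monotonic_positions_lower_median(self, small_image):
        # frame k displaced by k/2 voxels: positions 0, .5, ..., 4.5;
        # the lower median is position 2.0, i.e. frame 4
        series = self._series_with_shifts(small_image, [k * 0.5 for k in range(10)])
        assert select_reference_frame(series, 10) == 4

    def test_requires_at_least_three(self, small_image):
        series = self._series_with_shifts(small_image, [0.0] * 10)
        with pytest.raises(ValueError, match="n_initial"):
            select_reference_frame(series, 2)


class TestFlowBasis:
    def test_rank_one_family(self):
        grid = (1, 16, 16)
        base = FlowField(_smooth_field(grid, 5, 1.0), _smooth_field(grid, 6, 1.0))
        flows = [base * a for a in (-2.0, -1.0, 1.0, 2.0)]
        basis = build_flow_basis(flows)
        assert basis.n_retained == 1
        assert basis.explained_variance[0] > 0.999
        # component parallel to the generating field
        c = basis.components[0].flatten()
        b = base.flatten()
        cos = abs(c @ b) / (np.linalg.norm(c) * np.linalg.norm(b))
        assert cos > 0.9999

    def test_two_orthogonal_patterns_variance_split(self):
        """Explained variance must match the coefficient variances of two
        orthogonal generating patterns (oracle: eigendecomposition of the
        2x2 coefficient covariance)."""
        grid = (1, 8, 8)
        n = int(np.prod(grid))
        p1 = np.zeros(2 * n)
        p1[:n] = 1.0 / np.sqrt(n)
        p2 = np.zeros(2 * n)
        p2[n:] = 1.0 / np.sqrt(n)
        rng = np.random.default_rng(0)
        w1 = 3.0 * rng.standard_normal(12)
        w2 = 1.0 * rng.standard_normal(12)
        flows = [
            FlowField.from_vector(a * p1 + b * p2, grid) for a, b in zip(w1, w2)
        ]
        basis = build_flow_basis(flows, variance_threshold=0.999999)
        assert basis.n_retained == 2
        # oracle: eigenvalues of the exact 2x2 coefficient covariance
        cov = np.cov(np.stack([w1, w2]), ddof=0)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        expected = eig / eig.sum()
        assert np.allclose(basis.explained_variance, expected, atol=1e-10)
        assert basis.components[0].flatten() @ basis.components[1].flatten() == pytest.approx(0.0, abs=1e-10)

    def test_identical_flows_zero_components(self):
        grid = (1, 8, 8)
        f = FlowField(np.ones(grid), np.zeros(grid))
        with pytest.warns(RuntimeWarning, match="identical"):
            basis = build_flow_basis([f] * 15)
        assert basis.n_retained == 0
        assert np.allclose(basis.mean_flow.u, 1.0)

    def test_needs_two_flows(self):
        with pytest.raises(ValueError, match="2 flows"):
            build_flow_basis([FlowField.zeros((1, 4, 4))])


class TestPcaFlow:
    def _basis_from_field(self, field):
        return FlowBasis(
            mean_flow=FlowField.zeros(field.grid_shape), components=[field]
        )

    def test_recovers_in_span_coefficient(self, smooth_image):
        grid = (1, 128, 128)
        comp = FlowField(
            np.zeros(grid), 1.0 + _smooth_field(grid, 9, scale=0.3, sigma=40)
        )
        basis = self._basis_from_field(comp)
        # moving warped by the approximate inverse of 1.5*comp, so its
        # registration flow to the reference is 1.5*comp
        inv = FlowField(-1.5 * comp.u, -1.5 * comp.v)
        moving, _ = warp_image(smooth_image, inv)
        flow, a = estimate_flow_pca(moving, smooth_image, basis)
        assert a[0] == pytest.approx(1.5, abs=0.1)
        interior = np.s_[0, 10:-10, 10:-10]
        aee = np.mean(
            np.hypot(flow.u - 1.5 * comp.u, flow.v - 1.5 * comp.v)[interior]
        )
        assert aee < 0.1

    def test_output_lies_in_span(self, smooth_image):
        grid = (1, 128, 128)
        basis = FlowBasis(
            mean_flow=FlowField.zeros(grid),
            components=[
                FlowField(np.zeros(grid), np.full(grid, 1.0)),
            ],
        )
        moving = np.roll(smooth_image, 1, axis=0)
        flow, a = estimate_flow_pca(moving, smooth_image, basis)
        rebuilt = basis.reconstruct(a)
        assert np.max(np.abs(flow.u - rebuilt.u)) < 1e-10
        assert np.max(np.abs(flow.v - rebuilt.v)) < 1e-10

    def test_empty_basis_returns_mean_flow(self, small_image):
        grid = (1, 64, 64)
        basis = FlowBasis(mean_flow=_const_flow(grid, u=0.25))
        with pytest.warns(RuntimeWarning, match="empty basis"):
            flow, a = estimate_flow_pca(small_image, small_image, basis)
        assert a.size == 0
        assert np.allclose(flow.u, 0.25)

    def test_immune_to_hotspot_dropout(self, smooth_image):
        """Zero true motion plus a 50% intensity well: the constrained
        fit cannot express the localized spurious deformation."""
        grid = (1, 128, 128)
        rows, cols = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        disc = np.exp(-((rows - 64) ** 2 + (cols - 64) ** 2) / (2 * 4.0**2))
        moving = smooth_image * (1.0 - 0.5 * disc)
        comp = FlowField(np.zeros(grid), np.full(grid, 1.0))
        basis = self._basis_from_field(comp)
        flow, _ = estimate_flow_pca(moving, smooth_image, basis)
        assert flow.magnitude()[0][disc > 0.1].max() < 0.2

    def test_agrees_with_hs_for_in_span_motion(self, smooth_image):
        moving = np.roll(smooth_image, 1, axis=1)
        grid = (1, 128, 128)
        basis = FlowBasis(
            mean_flow=FlowField.zeros(grid),
            components=[FlowField(np.full(grid, 1.0), np.zeros(grid))],
        )
        f_pca, _ = estimate_flow_pca(moving, smooth_image, basis)
        f_hs = estimate_flow_hs(moving, smooth_image)
        interior = np.s_[0, 10:-10, 10:-10]
        aee = np.mean(
            np.hypot(f_pca.u - f_hs.u, f_pca.v - f_hs.v)[interior]
        )
        assert aee < 0.2
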