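"""Diffusion operator: coefficients, stencils, Euler scheme, stability."""

import numpy as np
import pytest

from gaborlift import (DiffusionConfig, LiftedResponse, apply_operator,
                       coherence_coefficients, euler_step, lift_mask,
                       make_feature_grid, offset_vectors, run_diffusion,
                       second_derivatives, spline_sample)
from gaborlift.diffusion import x3x3_combined_offset


class TestCoefficients:
    def test_study_sizes(self):
        b2, b3, b4 = coherence_coefficients(128, 32, 12, 5)
        assert b2 == pytest.approx(32 / 128**2)
        assert b3 == pytest.approx(12 / 128**2)
        assert b4 == pytest.approx(5 / 128**2)

    def test_degenerate_unit(self):
        assert coherence_coefficients(1, 1, 1, 1) == (1.0, 1.0, 1.0)

    def test_linear_in_counts(self):
        b2a, b3a, b4a = coherence_coefficients(64, 8, 3, 5)
        b2b, b3b, b4b = coherence_coefficients(64, 16, 3, 5)
        assert b2b == pytest.approx(2 * b2a)
        assert (b3b, b4b) == (b3a, b4a)


class TestOffsetVectors:
    @pytest.mark.parametrize("theta,exi,eeta", [
        (0.0, (1, 0), (0, 1)),
        (np.pi / 2, (0, 1), (-1, 0)),
    ])
    def test_closed_forms(self, theta, exi, eeta):
        ex, ee = offset_vectors(theta)
        assert np.allclose(ex, exi, atol=1e-12)
        assert np.allclose(ee, eeta, atol=1e-12)

    def test_orthogonal_for_all_angles(self):
        for theta in np.linspace(0, np.pi, 17):
            ex, ee = offset_vectors(theta)
            assert abs(ex @ ee) < 1e-14
            assert np.hypot(*ex) == pytest.approx(1.0)


class TestSplineSample:
    def test_reproduces_grid_values(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((16, 16))
        pts = [(3.0, 4.0), (10.0, 2.0), (15.0, 15.0)]
        got = spline_sample(u, pts, order=3)
        assert np.allclose(got, [u[3, 4], u[10, 2], u[15, 15]], atol=1e-10)

    def test_linear_field_exact_in_interior(self):
        # boundary-extension transients decay geometrically; interior exact
        x, y = np.meshgrid(np.arange(32.0), np.arange(32.0), indexing="ij")
        u = 2 * x - 3 * y + 1
        pts = [(15.3, 16.8), (16.5, 14.25)]
        got = spline_sample(u, pts, order=3)
        want = [2 * 15.3 - 3 * 16.8 + 1, 2 * 16.5 - 3 * 14.25 + 1]
        assert np.allclose(got, want, atol=1e-6)

    def test_smooth_field_against_analytic(self):
        x, y = np.meshgrid(np.arange(64.0), np.arange(64.0), indexing="ij")
        u = np.sin(0.2 * x) * np.cos(0.3 * y)
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.uniform(5, 58, 100), rng.uniform(5, 58, 100)])
        got = spline_sample(u, pts, order=3)
        want = np.sin(0.2 * pts[:, 0]) * np.cos(0.3 * pts[:, 1])
        assert np.max(np.abs(got - want)) < 1e-3

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            spline_sample(np.zeros((8, 8)), [(20.0, 0.0)])


class TestSecondDerivatives:
    def test_constant_field_all_zero(self, small_grid):
        shape = (16, 16, small_grid.K, small_grid.L, small_grid.M)
        u = np.full(shape, 2.5 + 0.5j)
        for d in second_derivatives(u, small_grid):
            assert np.allclose(d, 0.0, atol=1e-10)

    def test_x1x1_of_quadratic_matches_closed_form(self, small_grid):
        """X1X1 x^2 = 2 cos^2(theta); splines reproduce quadratics interior."""
        N = 48
        x = np.arange(N, dtype=float)
        u2d = np.broadcast_to((x**2)[:, None], (N, N))
        shape = (N, N, small_grid.K, small_grid.L, small_grid.M)
        u = np.broadcast_to(u2d[:, :, None, None, None], shape).astype(complex)
        D11, _, _, _ = second_derivatives(u, small_grid)
        inner = slice(16, -16)
        for k in range(small_grid.K):
            want = 2 * np.cos(small_grid.theta[k]) ** 2
            got = D11[inner, inner, k].real
            assert np.allclose(got, want, atol=1e-6), f"k={k}"

    def test_x3x3_reduces_to_phase_ramp_term(self):
        """Spatially constant phase ramp: D33 = f^2 * second phase difference."""
        grid = make_feature_grid(4, 2, 8, 0.5, 1.0, s_step=2 * np.pi / 8)
        # u = exp(i * phi_m) along the phase axis, constant otherwise
        ramp = np.exp(1j * grid.phi)
        shape = (16, 16, grid.K, grid.L, grid.M)
        u = np.broadcast_to(ramp[None, None, None, None, :], shape).copy()
        _, _, D33, _ = second_derivatives(u, grid)
        ds = grid.delta_s
        # analytic centered second difference of exp(i m ds) with wrap
        factor = (np.exp(1j * ds) - 2 + np.exp(-1j * ds)) / ds**2
        for l, f in enumerate(grid.f):
            want = f**2 * factor * ramp
            got = D33[8, 8, 0, l, :]
            assert np.allclose(got, want, atol=1e-10)

    def test_expanded_stencil_matches_combined_offset(self):
        """Expanded X3X3 agrees with the directional stencil at second order."""
        errs = []
        for scale in (1.0, 2.0):
            # refine every stencil scale together: spatial frequency, the
            # frequency coordinate (which multiplies d_s) and the phase step
            M = int(6 * scale)
            grid = make_feature_grid(3, 2, M, 0.4 / scale, 0.8 / scale,
                                     s_step=2 * np.pi / M)
            N = 24
            x, y = np.meshgrid(np.arange(N, dtype=float),
                               np.arange(N, dtype=float), indexing="ij")
            phases = np.exp(1j * grid.phi)
            smooth = np.exp(1j * (0.2 / scale) * (x + 0.5 * y))
            u = (smooth[:, :, None, None, None]
                 * phases[None, None, None, None, :])
            u = np.broadcast_to(u, (N, N, grid.K, grid.L, grid.M)).copy()
            _, _, D33, _ = second_derivatives(u, grid)
            alt = x3x3_combined_offset(u, grid, eps=1.0)
            inner = slice(8, -8)
            errs.append(np.max(np.abs(D33 - alt)[inner, inner]))
        # both are O(h^2)-consistent: the discrepancy shrinks ~4x when the
        # field is twice as smooth relative to the stencil
        assert errs[1] < errs[0] / 2.5

    def test_non_finite_input_rejected(self, small_grid):
        shape = (8, 8, small_grid.K, small_grid.L, small_grid.M)
        u = np.zeros(shape, complex)
        u[0, 0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            second_derivatives(u, small_grid)


class TestOperator:
    def test_constant_is_steady_state(self, small_grid):
        shape = (12, 12, small_grid.K, small_grid.L, small_grid.M)
        u = np.full(shape, 1.0 - 2.0j)
        for mode in ("exact", "approximate"):
            out = apply_operator(u, small_grid, DiffusionConfig(mode=mode))
            assert np.allclose(out, 0.0, atol=1e-10)

    def test_exact_with_tiny_betas_equals_approximate(self, small_grid):
        rng = np.random.default_rng(4)
        shape = (12, 12, small_grid.K, small_grid.L, small_grid.M)
        u = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        tiny = 1e-300
        exact = apply_operator(u, small_grid,
                               DiffusionConfig(mode="exact", beta3=tiny, beta4=tiny))
        approx = apply_operator(u, small_grid, DiffusionConfig(mode="approximate"))
        assert np.array_equal(exact, approx)

    def test_diffusion_flattens_a_bump(self, small_grid):
        """L~u < 0 at the peak of a spatial Gaussian bump (single channel)."""
        N = 24
        x, y = np.meshgrid(np.arange(N, dtype=float), np.arange(N, dtype=float),
                           indexing="ij")
        bump = np.exp(-((x - 12) ** 2 + (y - 12) ** 2) / 8.0)
        shape = (N, N, small_grid.K, small_grid.L, small_grid.M)
        u = np.zeros(shape, complex)
        u[:, :, 2, 1, 0] = bump
        out = apply_operator(u, small_grid, DiffusionConfig(mode="approximate"))
        assert out[12, 12, 2, 1, 0].real < 0


class TestEulerAndRun:
    def _setup(self, grid, N=16, seed=0):
        rng = np.random.default_rng(seed)
        shape = (N, N, grid.K, grid.L, grid.M)
        u0 = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        return u0

    def test_all_boundary_restores_exactly(self, small_grid):
        u0 = self._setup(small_grid)
        u = u0 + 3.0  # arbitrary drifted state
        mask = np.zeros(u0.shape, bool)
        cfg = DiffusionConfig()
        out = euler_step(u, u0, mask, small_grid, cfg)
        assert np.array_equal(out, u0)

    def test_constant_fixed_point_any_mask(self, small_grid):
        shape = (12, 12, small_grid.K, small_grid.L, small_grid.M)
        u0 = np.full(shape, 0.7 + 0.1j)
        mask = np.zeros(shape, bool)
        mask[4:8] = True
        out = euler_step(u0.copy(), u0, mask, small_grid, DiffusionConfig())
        assert np.allclose(out, u0, atol=1e-12)

    def test_masked_impulse_moves_toward_neighbors(self, small_grid):
        """One masked impulse relaxes; near-maximum principle holds."""
        rng = np.random.default_rng(9)
        for trial in range(3):
            shape = (12, 12, small_grid.K, small_grid.L, small_grid.M)
            u0 = 0.2 * (rng.standard_normal(shape)
                        + 1j * rng.standard_normal(shape))
            spot = (6, 6)
            mask = np.zeros(shape, bool)
            mask[spot] = True
            u0[spot] += 2.0  # impulse on the masked site
            out = euler_step(u0.copy(), u0, mask, small_grid, DiffusionConfig())
            # impulse shrinks toward surrounding values
            assert np.all(np.abs(out[spot]) < np.abs(u0[spot]))
            assert np.max(np.abs(out)) <= 1.05 * np.max(np.abs(u0))

    def test_nan_aborts_with_stability_error(self, small_grid):
        u0 = self._setup(small_grid, N=12)
        mask = np.ones(u0.shape, bool)
        huge_dt = DiffusionConfig(dt=1e300, T=1e300)
        with pytest.raises(FloatingPointError, match="dt"), \
                np.errstate(over="ignore", invalid="ignore"):
            u = u0.copy()
            for _ in range(4):
                u = euler_step(u, u0, mask, small_grid, huge_dt)

    def test_empty_mask_returns_input_bit_exact(self, small_grid):
        u0 = self._setup(small_grid)
        resp = LiftedResponse(values=u0, grid=small_grid)
        mask = np.zeros(u0.shape, bool)
        run = run_diffusion(resp, mask, small_grid, DiffusionConfig(T=1.0))
        assert np.array_equal(run.response.values, u0)
        assert run.iterations == 0

    def test_zero_input_stays_zero(self, small_grid):
        shape = (12, 12, small_grid.K, small_grid.L, small_grid.M)
        resp = LiftedResponse(values=np.zeros(shape, complex), grid=small_grid)
        mask = lift_mask(np.eye(12, dtype=bool), small_grid.K, small_grid.L,
                         small_grid.M)
        run = run_diffusion(resp, mask, small_grid, DiffusionConfig(T=2.0))
        assert np.all(run.response.values == 0)

    def test_relaxation_eventually_monotone(self, small_grid):
        """Per-step L2 change is non-increasing over the last 80% of steps."""
        rng = np.random.default_rng(21)
        N = 16
        shape = (N, N, small_grid.K, small_grid.L, small_grid.M)
        u0 = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        resp = LiftedResponse(values=u0, grid=small_grid)
        spatial = np.zeros((N, N), bool)
        spatial[5:11, 5:11] = True
        mask = lift_mask(spatial, small_grid.K, small_grid.L, small_grid.M)
        run = run_diffusion(resp, mask, small_grid,
                            DiffusionConfig(mode="approximate", T=5.0))
        tail = run.changes[int(0.2 * len(run.changes)):]
        assert np.all(np.diff(tail) <= 1e-12)

    def test_early_stop_on_steady_state(self, small_grid):
        shape = (12, 12, small_grid.K, small_grid.L, small_grid.M)
        u0 = np.full(shape, 1.0 + 0j)
        resp = LiftedResponse(values=u0, grid=small_grid)
        spatial = np.zeros((12, 12), bool)
        spatial[4:6] = True
        mask = lift_mask(spatial, small_grid.K, small_grid.L, small_grid.M)
        run = run_diffusion(resp, mask, small_grid,
                            DiffusionConfig(T=50.0, stop_tol=1e-12))
        assert run.iterations < 500
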