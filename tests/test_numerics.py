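"""Tridiagonal solves, Poisson solve, ADI transport, wall conditions."""

import numpy as np
import pytest

import bioconvect as bc
from bioconvect.errors import (
    InvalidInputError,
    SingularSystemError,
    UnstableStepError,
)
from bioconvect.model_core import basic_state_n
from bioconvect.numerics import (
    TransportCoeffs,
    TriDiagSystem,
    adi_advance_scalar,
    apply_micro_bcs,
    apply_nano_bcs,
    apply_theta_dirichlet,
    apply_wall_vorticity,
    laplacian_interior,
    solve_poisson_stream,
    solve_tridiagonal,
)
from bioconvect.simulation import build_theta_boundary


class TestTridiagonal:
    def test_identity_system(self, rng):
        r = rng.standard_normal(8)
        sys = TriDiagSystem(np.zeros(8), np.ones(8), np.zeros(8), r)
        assert np.allclose(solve_tridiagonal(sys), r)

    def test_matches_dense_solve(self):
        # oracle: Gaussian elimination on the dense matrix
        sys = TriDiagSystem(
            lower=np.array([0.0, -1.0, -1.0]),
            diag=np.array([2.0, 2.0, 2.0]),
            upper=np.array([-1.0, -1.0, 0.0]),
            rhs=np.array([1.0, 0.0, 1.0]),
        )
        dense = np.array([[2.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 2.0]])
        assert np.allclose(solve_tridiagonal(sys), np.linalg.solve(dense, sys.rhs))

    def test_linearity(self, rng):
        m = 12
        a = rng.uniform(-1, 0, m)
        b = rng.uniform(3, 4, m)
        c = rng.uniform(-1, 0, m)
        r1, r2 = rng.standard_normal(m), rng.standard_normal(m)
        x12 = solve_tridiagonal(TriDiagSystem(a, b, c, r1 + r2))
        x1 = solve_tridiagonal(TriDiagSystem(a, b, c, r1))
        x2 = solve_tridiagonal(TriDiagSystem(a, b, c, r2))
        assert np.allclose(x12, x1 + x2, atol=1e-13)

    def test_residual_contract(self, rng):
        m = 50
        a = rng.uniform(-1, 0, m)
        b = rng.uniform(3, 4, m)
        c = rng.uniform(-1, 0, m)
        r = rng.standard_normal(m)
        x = solve_tridiagonal(TriDiagSystem(a, b, c, r))
        resid = np.copy(b * x)
        resid[1:] += a[1:] * x[:-1]
        resid[:-1] += c[:-1] * x[1:]
        assert np.max(np.abs(resid - r)) <= 1e-10 * np.max(np.abs(r))

    def test_zero_pivot_raises(self):
        sys = TriDiagSystem(
            np.array([0.0, 1.0]), np.array([0.0, 1.0]),
            np.array([1.0, 0.0]), np.array([1.0, 1.0]),
        )
        with pytest.raises(SingularSystemError):
            solve_tridiagonal(sys)


class TestPoissonStream:
    def test_zero_vorticity_gives_zero_stream(self, small_grid):
        psi = solve_poisson_stream(np.zeros(small_grid.shape), small_grid)
        assert not np.any(psi)

    def test_manufactured_solution_second_order(self):
        # psi* = sin(pi x1/A) sin(pi x2), omega = pi^2 (1/A^2 + 1) psi*
        errs = []
        for nx in (17, 33, 65):
            g = bc.make_grid(nx, nx, 5.0)
            x1, x2 = g.mesh()
            psi_star = np.sin(np.pi * x1 / g.A) * np.sin(np.pi * x2)
            omega = np.pi**2 * (1.0 / g.A**2 + 1.0) * psi_star
            psi = solve_poisson_stream(omega, g)
            errs.append(np.max(np.abs(psi - psi_star)))
        rate1 = errs[0] / errs[1]
        rate2 = errs[1] / errs[2]
        assert 3.3 < rate1 < 4.7 and 3.3 < rate2 < 4.7

    def test_boundary_exactly_zero_and_linearity(self, small_grid, rng):
        omega = rng.standard_normal(small_grid.shape)
        psi = solve_poisson_stream(omega, small_grid)
        assert not np.any(psi[0, :]) and not np.any(psi[-1, :])
        assert not np.any(psi[:, 0]) and not np.any(psi[:, -1])
        psi2 = solve_poisson_stream(2.0 * omega, small_grid)
        assert np.allclose(psi2, 2.0 * psi, atol=1e-12)

    def test_discrete_laplacian_matches_forcing(self, small_grid, rng):
        omega = rng.standard_normal(small_grid.shape)
        psi = solve_poisson_stream(omega, small_grid)
        res = laplacian_interior(psi, small_grid) + omega[1:-1, 1:-1]
        assert np.max(np.abs(res)) < 1e-8


def _hold_dirichlet_sides_neumann(f):
    """Side walls copy (zero x1-gradient), top/bottom held at zero."""
    f[0, :] = (4.0 * f[1, :] - f[2, :]) / 3.0
    f[-1, :] = (4.0 * f[-2, :] - f[-3, :]) / 3.0
    f[:, 0] = 0.0
    f[:, -1] = 0.0


class TestADITransport:
    def test_uniform_field_is_steady(self, small_grid):
        g = small_grid
        f = np.full(g.shape, 3.7)
        zero = np.zeros(g.shape)
        out = adi_advance_scalar(
            f, zero, zero, TransportCoeffs(1.0), 1e-3, g,
            bc=lambda a: None,
        )
        assert np.allclose(out, 3.7, atol=1e-13)

    def test_heat_mode_decay_rate(self):
        # sin(pi x2) with Dirichlet 0 decays as exp(-D pi^2 t)
        g = bc.make_grid(9, 81, 1.0)
        x1, x2 = g.mesh()
        f = np.sin(np.pi * x2)
        zero = np.zeros(g.shape)
        D, dt, nsteps = 1.0, 1e-4, 1000
        coeffs = TransportCoeffs(D)
        for _ in range(nsteps):
            f = adi_advance_scalar(
                f, zero, zero, coeffs, dt, g, bc=_hold_dirichlet_sides_neumann
            )
        amp = np.max(f)
        expected = np.exp(-D * np.pi**2 * dt * nsteps)
        assert amp == pytest.approx(expected, rel=0.01)

    def test_agrees_with_explicit_euler_to_second_order(self, rng):
        # oracle: monolithic forward-Euler step of the same semi-discretisation
        g = bc.make_grid(7, 7, 1.0)
        x1, x2 = g.mesh()
        f0 = 1.0 + 0.3 * np.sin(np.pi * x1) * np.sin(np.pi * x2)
        u = 0.5 * np.cos(np.pi * x1) * np.sin(2 * np.pi * x2)
        v = -0.4 * np.sin(2 * np.pi * x1) * np.cos(np.pi * x2)
        S = 0.2 * np.cos(np.pi * x1 * x2)
        swim, D = 0.7, 0.8
        veff = v + swim

        def euler(f, dt):
            out = f.copy()
            adv1 = (u[2:, 1:-1] * f[2:, 1:-1] - u[:-2, 1:-1] * f[:-2, 1:-1]) / (
                2 * g.dx1
            )
            adv2 = (veff[1:-1, 2:] * f[1:-1, 2:] - veff[1:-1, :-2] * f[1:-1, :-2]) / (
                2 * g.dx2
            )
            out[1:-1, 1:-1] += dt * (
                -adv1 - adv2 + D * laplacian_interior(f, g) + S[1:-1, 1:-1]
            )
            return out

        errs = []
        for dt in (2e-3, 1e-3):
            adi = adi_advance_scalar(
                f0.copy(), u, v, TransportCoeffs(D, swim, S), dt, g, bc=None
            )
            errs.append(np.max(np.abs(adi - euler(f0, dt))))
        order = np.log2(errs[0] / errs[1])
        assert order >= 1.9

    def test_manufactured_diffusion_second_order_in_space(self):
        # steady manufactured solution of pure diffusion with a source:
        # f* = sin(pi x1) sin(pi x2), S = 2 pi^2 D f*; march to steady state
        errs = []
        for nx in (9, 17):
            g = bc.make_grid(nx, nx, 1.0)
            x1, x2 = g.mesh()
            fstar = np.sin(np.pi * x1) * np.sin(np.pi * x2)
            S = 2.0 * np.pi**2 * fstar
            zero = np.zeros(g.shape)
            f = np.zeros(g.shape)
            coeffs = TransportCoeffs(1.0, 0.0, S)

            def hold_zero(a):
                a[0, :] = a[-1, :] = 0.0
                a[:, 0] = a[:, -1] = 0.0

            for _ in range(4000):
                f = adi_advance_scalar(f, zero, zero, coeffs, 2e-3, g, bc=hold_zero)
            errs.append(np.max(np.abs(f - fstar)))
        assert 3.0 < errs[0] / errs[1] < 5.5

    def test_large_diffusive_step_is_stable(self):
        # 100x the explicit diffusive limit: no blow-up, monotone decay
        g = bc.make_grid(33, 33, 1.0)
        x1, x2 = g.mesh()
        f = np.sin(np.pi * x1) * np.sin(np.pi * x2)
        zero = np.zeros(g.shape)
        dt_expl = 0.25 * min(g.dx1, g.dx2) ** 2
        coeffs = TransportCoeffs(1.0)

        def hold_zero(a):
            a[0, :] = a[-1, :] = 0.0
            a[:, 0] = a[:, -1] = 0.0

        amps = [np.max(np.abs(f))]
        for _ in range(20):
            f = adi_advance_scalar(f, zero, zero, coeffs, 100 * dt_expl, g, bc=hold_zero)
            amps.append(np.max(np.abs(f)))
        assert np.all(np.isfinite(f))
        assert np.all(np.diff(amps) <= 1e-14)

    def test_strong_advection_raises_unstable(self, small_grid):
        g = small_grid
        f = np.ones(g.shape)
        u = np.full(g.shape, 1e4)
        zero = np.zeros(g.shape)
        with pytest.raises(UnstableStepError):
            adi_advance_scalar(f, u, zero, TransportCoeffs(1e-3), 0.1, g, bc=None)

    def test_rejects_nonpositive_dt_and_diffusivity(self, small_grid):
        zero = np.zeros(small_grid.shape)
        with pytest.raises(InvalidInputError):
            adi_advance_scalar(zero, zero, zero, TransportCoeffs(1.0), -1e-3, small_grid)
        with pytest.raises(InvalidInputError):
            TransportCoeffs(0.0)


class TestWallVorticity:
    def test_rest_state(self, small_grid):
        omega = np.ones(small_grid.shape)
        apply_wall_vorticity(np.zeros(small_grid.shape), omega, small_grid)
        assert not np.any(omega[:, 0]) and not np.any(omega[:, -1])
        assert not np.any(omega[0, :]) and not np.any(omega[-1, :])

    def test_quadratic_boundary_layer(self):
        # psi = x2^2 near the bottom wall: Thom reproduces -d2psi/dx2^2 = -2
        g = bc.make_grid(11, 11, 1.0)
        x1, x2 = g.mesh()
        psi = x2**2
        omega = np.zeros(g.shape)
        apply_wall_vorticity(psi, omega, g)
        assert np.allclose(omega[1:-1, 0], -2.0)

    def test_linearity_in_psi(self, small_grid, rng):
        psi = rng.standard_normal(small_grid.shape)
        psi[0, :] = psi[-1, :] = psi[:, 0] = psi[:, -1] = 0.0
        om1 = apply_wall_vorticity(psi, np.zeros(small_grid.shape), small_grid)
        om3 = apply_wall_vorticity(3.0 * psi, np.zeros(small_grid.shape), small_grid)
        assert np.allclose(om3, 3.0 * om1)


class TestFluxBCs:
    def test_zero_peclet_reduces_to_reflection(self, small_grid):
        p = bc.SimulationParams(Pe=0.0, Pen=0.0)
        n = np.ones(small_grid.shape) * 1.3
        apply_micro_bcs(n, p, small_grid)
        assert np.allclose(n, 1.3)

    def test_basic_state_satisfies_discrete_micro_bc(self):
        # the exponential rest profile obeys Pe*n - dn/dx2 = 0 at the walls
        g = bc.make_grid(5, 161, 5.0)
        p = bc.SimulationParams()
        nb = np.broadcast_to(basic_state_n(g.x2, p.Pe, p.Nbar), g.shape).copy()
        before = nb.copy()
        apply_micro_bcs(nb, p, g)
        assert np.max(np.abs(nb - before)) < 2e-5  # truncation-order agreement

    def test_theta_walls_zero_without_sources(self, small_grid):
        theta = np.ones(small_grid.shape)
        bmap = build_theta_boundary([], small_grid)
        apply_theta_dirichlet(theta, bmap)
        assert not np.any(theta[:, 0]) and not np.any(theta[:, -1])
        assert not np.any(theta[0, :]) and not np.any(theta[-1, :])
        assert np.all(theta[1:-1, 1:-1] == 1.0)

    def test_nano_bc_balances_thermophoresis(self, small_grid):
        # with Pen = 0 and a linear theta profile, the wall condition gives
        # dBm dphi/dx2 = -dTm dtheta/dx2 exactly for linear profiles
        g = small_grid
        p = bc.SimulationParams(Pen=0.0, delta_Bm=0.5, delta_Tm=0.2)
        x1, x2 = g.mesh()
        theta = x2.copy()
        slope = -p.delta_Tm / p.delta_Bm
        phi = 1.0 + slope * x2
        before = phi.copy()
        apply_nano_bcs(phi, theta, p, g)
        assert np.allclose(phi, before, atol=1e-12)
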