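"""Discrete operators: tridiagonal solves, the stream-function Poisson
solve, ADI transport half-steps and all boundary-condition enforcement.

Spatial discretisation is second-order centred throughout; advection uses
the conservative flux form with the velocity evaluated at neighbour
nodes, which together with the discretely divergence-free velocity makes
the interior stencil a telescoping sum of half-cell face fluxes.  Wall
conditions for the transported scalars are zero-total-flux closures at
the first half-cell face, folded into the implicit line solves, so the
interior content of microorganisms and nanoparticles is conserved to
rounding; wall-node values are slaved to the closures (no ghost rows).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.fft import dstn, idstn

from . import _kernels
from .errors import (
    InvalidInputError,
    IterativeFailureError,
    SingularSystemError,
    UnstableStepError,
)
from .model_core import FieldState, Grid, SimulationParams

__all__ = [
    "TriDiagSystem",
    "TransportCoeffs",
    "solve_tridiagonal",
    "solve_poisson_stream",
    "adi_advance_scalar",
    "apply_wall_vorticity",
    "apply_flux_bcs",
    "apply_theta_dirichlet",
    "apply_micro_bcs",
    "apply_nano_bcs",
    "micro_line_closures",
    "nano_line_closures",
    "laplacian_interior",
]


@dataclass
class TriDiagSystem:
    """One tridiagonal line system A x = rhs.

    ``lower[0]`` and ``upper[-1]`` are ignored, matching the usual
    banded-storage convention.
    """

    lower: np.ndarray
    diag: np.ndarray
    upper: np.ndarray
    rhs: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.diag = np.asarray(self.diag, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.rhs = np.asarray(self.rhs, dtype=float)
        m = self.diag.size
        if m < 1 or any(v.size != m for v in (self.lower, self.upper, self.rhs)):
            raise InvalidInputError("tridiagonal bands and rhs must share length >= 1")


def solve_tridiagonal(sys: TriDiagSystem) -> np.ndarray:
    """Thomas elimination with an explicit zero-pivot guard."""
    a, b, c, d = sys.lower, sys.diag, sys.upper, sys.rhs
    m = b.size
    scale = max(np.max(np.abs(b)), 1.0)
    cp = np.empty(m)
    dp = np.empty(m)
    beta = b[0]
    if abs(beta) <= 1e-300 * scale:
        raise SingularSystemError("zero pivot at row 0")
    cp[0] = c[0] / beta
    dp[0] = d[0] / beta
    for k in range(1, m):
        beta = b[k] - a[k] * cp[k - 1]
        if abs(beta) <= 1e-300 * scale:
            raise SingularSystemError(f"zero pivot at row {k}")
        cp[k] = c[k] / beta
        dp[k] = (d[k] - a[k] * dp[k - 1]) / beta
    x = np.empty(m)
    x[m - 1] = dp[m - 1]
    for k in range(m - 2, -1, -1):
        x[k] = dp[k] - cp[k] * x[k + 1]
    return x


def laplacian_interior(f: np.ndarray, g: Grid) -> np.ndarray:
    """Standard 5-point Laplacian on interior nodes (shape (Nx1-2, Nx2-2))."""
    return (f[2:, 1:-1] - 2.0 * f[1:-1, 1:-1] + f[:-2, 1:-1]) / g.dx1**2 + (
        f[1:-1, 2:] - 2.0 * f[1:-1, 1:-1] + f[1:-1, :-2]
    ) / g.dx2**2


@lru_cache(maxsize=32)
def _poisson_eigenvalues(Nx1: int, Nx2: int, dx1: float, dx2: float) -> np.ndarray:
    m1, m2 = Nx1 - 2, Nx2 - 2
    lam1 = (2.0 * np.cos(np.pi * np.arange(1, m1 + 1) / (m1 + 1)) - 2.0) / dx1**2
    lam2 = (2.0 * np.cos(np.pi * np.arange(1, m2 + 1) / (m2 + 1)) - 2.0) / dx2**2
    return lam1[:, None] + lam2[None, :]


def solve_poisson_stream(
    omega: np.ndarray, g: Grid, tol: float = 1e-8
) -> np.ndarray:
    """Solve ``lap(psi) = -omega`` with psi = 0 on every wall.

    Direct fast sine-transform solve: the DST-I diagonalises the 5-point
    Dirichlet Laplacian on a uniform mesh, so the discrete system is
    solved to rounding error in one pass.  The residual is still checked
    against ``tol`` (relative to the forcing magnitude) to honour the
    operator contract.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape != g.shape:
        raise InvalidInputError("omega shape does not match grid")
    rhs = -omega[1:-1, 1:-1]
    lam = _poisson_eigenvalues(g.Nx1, g.Nx2, g.dx1, g.dx2)
    psi = np.zeros(g.shape)
    psi[1:-1, 1:-1] = idstn(dstn(rhs, type=1) / lam, type=1)
    res = np.max(np.abs(laplacian_interior(psi, g) + omega[1:-1, 1:-1]))
    bound = tol * max(1.0, float(np.max(np.abs(omega))))
    if not res <= bound:
        raise IterativeFailureError(
            f"Poisson residual {res:.3e} exceeds tolerance {bound:.3e}", residual=res
        )
    return psi


@dataclass
class TransportCoeffs:
    """Per-equation coefficients for the generic ADI transport step.

    ``diffusivity`` multiplies the Laplacian (Sc for vorticity, 1 for
    microorganisms, Le for temperature, delta_Bm for nanoparticles).
    ``swim_velocity`` adds a constant vertical advection speed (Pe for
    the upward-swimming microorganisms).  ``source_field`` is an explicit
    source evaluated on the full grid (only interior values are used).
    """

    diffusivity: float
    swim_velocity: float = 0.0
    source_field: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.diffusivity > 0:
            raise InvalidInputError(
                f"diffusivity must be positive, got {self.diffusivity!r}"
            )


def _fixed_wall_closure_x1(f: np.ndarray):
    z = np.zeros(f.shape[1])
    return z, f[0, :].astype(float), z, f[-1, :].astype(float)


def _fixed_wall_closure_x2(f: np.ndarray):
    z = np.zeros(f.shape[0])
    return z, f[:, 0].astype(float), z, f[:, -1].astype(float)


def adi_advance_scalar(
    f: np.ndarray,
    u: np.ndarray,
    v: np.ndarray,
    c: TransportCoeffs,
    dt: float,
    g: Grid,
    bc=None,
    closures=None,
) -> np.ndarray:
    """Advance one scalar by a full ADI step (x1-implicit then x2-implicit).

    Each half-step advances dt/2 with the other direction explicit; the
    boundary handler ``bc`` (an in-place callable on the field) runs after
    each half-step so wall values track the interior.

    ``closures`` optionally supplies linear wall closures
    ``(x1_closure, x2_closure)``, each a 4-tuple of per-line arrays
    ``(alpha_lo, gamma_lo, alpha_hi, gamma_hi)`` meaning
    ``f_wall = alpha * f_adjacent + gamma``; they are folded into the
    implicit line systems so flux-balance conditions hold at the new
    time level (exact conservation for the flux closures).  Without
    them the wall values are held fixed during each half-step.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    S = c.source_field
    if S is None:
        S = np.zeros(g.shape)
    veff = v + c.swim_velocity
    dt2 = 0.5 * dt
    x1c, x2c = closures if closures is not None else (None, None)
    fs, ok = _kernels.adi_half_x1(
        f, u, veff, c.diffusivity, S, dt2, g.dx1, g.dx2,
        *(x1c if x1c is not None else _fixed_wall_closure_x1(f)),
    )
    if not ok:
        raise UnstableStepError(
            "x1 line system lost diagonal dominance; reduce dt or refine the mesh"
        )
    if bc is not None:
        bc(fs)
    fn, ok = _kernels.adi_half_x2(
        fs, u, veff, c.diffusivity, S, dt2, g.dx1, g.dx2,
        *(x2c if x2c is not None else _fixed_wall_closure_x2(fs)),
    )
    if not ok:
        raise UnstableStepError(
            "x2 line system lost diagonal dominance; reduce dt or refine the mesh"
        )
    if bc is not None:
        bc(fn)
    return fn


def apply_wall_vorticity(psi: np.ndarray, omega: np.ndarray, g: Grid) -> np.ndarray:
    """Thom closure ``omega_wall = -2 psi_adj / h^2`` on all four walls.

    Modifies ``omega`` in place (and returns it).  Corner values take the
    side-wall closure, which is immaterial: corners never feed back into
    the interior stencils.
    """
    omega[:, 0] = -2.0 * psi[:, 1] / g.dx2**2
    omega[:, -1] = -2.0 * psi[:, -2] / g.dx2**2
    omega[0, :] = -2.0 * psi[1, :] / g.dx1**2
    omega[-1, :] = -2.0 * psi[-2, :] / g.dx1**2
    return omega


def apply_theta_dirichlet(theta: np.ndarray, theta_boundary: dict) -> np.ndarray:
    """Impose wall temperatures; bottom/top own the corner nodes so a
    source that reaches a corner keeps its value there."""
    theta[0, :] = theta_boundary["left"]
    theta[-1, :] = theta_boundary["right"]
    theta[:, 0] = theta_boundary["bottom"]
    theta[:, -1] = theta_boundary["top"]
    return theta


def micro_line_closures(
    p: SimulationParams,
    g: Grid,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
):
    """Linear wall closures ``n_wall = alpha n_adj`` zeroing the total
    microorganism flux (carried flow + swimming − diffusion) through the
    half-cell face next to each wall."""
    pe = p.Pe + (p.Pen if p.micro_bc_includes_pen else 0.0)
    h1, h2 = g.dx1, g.dx2
    n1, n2 = g.shape
    u1 = u[1, :] if u is not None else np.zeros(n2)
    uI1 = u[-2, :] if u is not None else np.zeros(n2)
    x1c = (
        1.0 - 0.5 * h1 * u1,
        np.zeros(n2),
        1.0 + 0.5 * h1 * uI1,
        np.zeros(n2),
    )
    v1 = v[:, 1] if v is not None else np.zeros(n1)
    vJ1 = v[:, -2] if v is not None else np.zeros(n1)
    x2c = (
        (1.0 / h2 - 0.5 * (v1 + pe)) / (1.0 / h2 + 0.5 * pe),
        np.zeros(n1),
        (1.0 / h2 + 0.5 * (vJ1 + pe)) / (1.0 / h2 - 0.5 * pe),
        np.zeros(n1),
    )
    return x1c, x2c


def apply_micro_bcs(
    n: np.ndarray,
    p: SimulationParams,
    g: Grid,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
) -> np.ndarray:
    """Microorganism wall conditions: zero total flux through every wall.

    Vertical flux ``(v + Pe) n - dn/dx2`` (upward swimming balanced by
    diffusion and carried flow; with ``micro_bc_includes_pen`` the
    swimming speed is ``Pe + Pen``), horizontal flux ``u n - dn/dx1``.
    Each condition is discretised at the half cell next to the wall —
    the identical flux the conservative interior stencil sees — so the
    two telescope: total content is conserved, and at rest the discrete
    exponential profile is an exact fixed point.  At rest (``u = v = 0``,
    the default) the side condition reduces to the plain Neumann form.
    """
    x1c, x2c = micro_line_closures(p, g, u, v)
    n[0, :] = x1c[0] * n[1, :]
    n[-1, :] = x1c[2] * n[-2, :]
    n[:, 0] = x2c[0] * n[:, 1]
    n[:, -1] = x2c[2] * n[:, -2]
    return n


def apply_nano_bcs(
    phi: np.ndarray,
    theta: np.ndarray,
    p: SimulationParams,
    g: Grid,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
) -> np.ndarray:
    """Nanoparticle wall conditions: zero total flux through every wall.

    The flux is carried flow plus Brownian diffusion plus thermophoretic
    drift, ``u_n phi - dBm dphi/dn - dTm dtheta/dn``, and each wall
    condition zeroes it at the half cell next to the wall — the
    identical flux the conservative interior stencil (with its
    ``dTm lap(theta)`` source) sees, so total nanoparticle content is
    conserved to rounding for any flow.  Dropping the thermophoretic
    part on any wall (the plain Neumann reading) would leak particles
    through every wall segment with a normal temperature gradient; the
    Neumann form is recovered exactly wherever the wall is adiabatic
    and the fluid at rest.  With ``nano_bc_includes_pen`` the vertical
    balance gains the settling term ``-Pen*phi`` of the printed Robin
    condition; the transport equation has no matching settling
    advection, so that variant leaks content and admits no steady state
    (see SimulationParams).
    """
    x1c, x2c = nano_line_closures(theta, p, g, u, v)
    phi[0, :] = x1c[0] * phi[1, :] + x1c[1]
    phi[-1, :] = x1c[2] * phi[-2, :] + x1c[3]
    phi[:, 0] = x2c[0] * phi[:, 1] + x2c[1]
    phi[:, -1] = x2c[2] * phi[:, -2] + x2c[3]
    return phi


def nano_line_closures(
    theta: np.ndarray,
    p: SimulationParams,
    g: Grid,
    u: np.ndarray | None = None,
    v: np.ndarray | None = None,
):
    """Linear wall closures ``phi_wall = alpha phi_adj + gamma`` zeroing
    the total nanoparticle flux (carried flow + Brownian diffusion +
    thermophoresis, optionally the printed settling term) through the
    half-cell face next to each wall."""
    dB, dT = p.delta_Bm, p.delta_Tm
    h1, h2 = g.dx1, g.dx2
    n1, n2 = g.shape
    u1 = u[1, :] if u is not None else np.zeros(n2)
    uI1 = u[-2, :] if u is not None else np.zeros(n2)
    # side faces: (u phi)_half - dB (dphi/dx1)_half - dT (dth/dx1)_half = 0
    x1c = (
        1.0 - 0.5 * h1 * u1 / dB,
        (dT / dB) * (theta[1, :] - theta[0, :]),
        1.0 + 0.5 * h1 * uI1 / dB,
        -(dT / dB) * (theta[-1, :] - theta[-2, :]),
    )
    Pen = p.Pen if p.nano_bc_includes_pen else 0.0
    v1 = v[:, 1] if v is not None else np.zeros(n1)
    vJ1 = v[:, -2] if v is not None else np.zeros(n1)
    den_b = dB / h2 + 0.5 * Pen
    den_t = dB / h2 - 0.5 * Pen
    # bottom/top faces: dB*(df/dx2)_half + dT*(dth/dx2)_half - ((v+Pen) f)_half = 0
    x2c = (
        (dB / h2 - 0.5 * (v1 + Pen)) / den_b,
        dT * (theta[:, 1] - theta[:, 0]) / h2 / den_b,
        (dB / h2 + 0.5 * (vJ1 + Pen)) / den_t,
        -dT * (theta[:, -1] - theta[:, -2]) / h2 / den_t,
    )
    return x1c, x2c


def apply_flux_bcs(
    state: FieldState,
    p: SimulationParams,
    g: Grid,
    theta_boundary: dict,
) -> FieldState:
    """Enforce every wall condition on a state in place.

    Temperature first (the nanoparticle closure reads its wall
    gradient), then microorganisms, nanoparticles, and the no-penetration
    stream-function condition.  The flux closures use the velocity
    recovered from the state's own stream function.
    """
    from .model_core import velocity_from_stream

    u, v = velocity_from_stream(state.psi, g)
    apply_theta_dirichlet(state.theta, theta_boundary)
    apply_micro_bcs(state.n, p, g, u, v)
    apply_nano_bcs(state.phi, state.theta, p, g, u, v)
    state.psi[0, :] = 0.0
    state.psi[-1, :] = 0.0
    state.psi[:, 0] = 0.0
    state.psi[:, -1] = 0.0
    return state
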