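"""Case setup, the full coupled time step, and iteration to steady state.

One time step advances the five fields in the order vorticity -> stream
function -> wall vorticity -> microorganisms -> temperature ->
nanoparticles, so the buoyancy forcing always uses scalars from one
common time level.  The run loop repeats steps until the largest
per-step change over all five fields drops below the convergence
tolerance (1e-6 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import DivergenceError, InvalidInputError, InvalidSourceError
from .model_core import (
    FieldState,
    Grid,
    SimulationParams,
    SourceSpec,
    init_basic_state,
    make_grid,
)
from .numerics import (
    TransportCoeffs,
    adi_advance_scalar,
    apply_flux_bcs,
    apply_micro_bcs,
    apply_nano_bcs,
    apply_theta_dirichlet,
    apply_wall_vorticity,
    micro_line_closures,
    nano_line_closures,
    solve_poisson_stream,
)

__all__ = [
    "CaseConfig",
    "RunResult",
    "CASE1_SOURCE",
    "CASE2_SOURCE",
    "build_theta_boundary",
    "time_step",
    "run_to_convergence",
]

#: Default heated segments for the two studied geometries: a source on
#: the left end of the bottom wall, and one centred on the left wall.
CASE1_SOURCE = SourceSpec(wall="bottom", start_frac=0.0, end_frac=0.1)
CASE2_SOURCE = SourceSpec(wall="left", start_frac=0.4, end_frac=0.6)


@dataclass
class CaseConfig:
    """Everything needed to reproduce one run."""

    params: SimulationParams = field(default_factory=SimulationParams)
    grid: Grid = field(default_factory=lambda: make_grid(101, 81, 5.0))
    sources: list[SourceSpec] = field(default_factory=lambda: [CASE1_SOURCE])
    dt: float = 1e-4
    epsilon: float = 1e-6
    max_iters: int = 400_000
    #: convergence is not tested before this many iterations; useful for
    #: warm-started continuation runs, where the first steps can sit
    #: below epsilon before a parameter change has had time to act
    min_iters: int = 1
    seed: int = 0
    perturbation_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise InvalidInputError("dt must be positive")
        if not self.epsilon > 0:
            raise InvalidInputError("epsilon must be positive")
        if self.max_iters < 1:
            raise InvalidInputError("max_iters must be at least 1")
        if self.min_iters < 1:
            raise InvalidInputError("min_iters must be at least 1")
        if abs(self.grid.A - self.params.A) > 1e-12:
            raise InvalidInputError(
                f"grid aspect ratio {self.grid.A} disagrees with params.A {self.params.A}"
            )

    def replace(self, **kw) -> "CaseConfig":
        from dataclasses import replace as _replace

        return _replace(self, **kw)


@dataclass
class RunResult:
    state: FieldState
    converged: bool
    iterations: int
    residual_history: np.ndarray
    diagnostics: dict


def build_theta_boundary(sources: list[SourceSpec], g: Grid) -> dict:
    """Wall temperature arrays: 0 everywhere except on source segments.

    Segment endpoints are rounded to the nearest node and included.
    Overlapping segments on one wall simply overwrite, which merges them.
    """
    bmap = {
        "bottom": np.zeros(g.Nx1),
        "top": np.zeros(g.Nx1),
        "left": np.zeros(g.Nx2),
        "right": np.zeros(g.Nx2),
    }
    for s in sources:
        if not isinstance(s, SourceSpec):
            raise InvalidSourceError(f"not a SourceSpec: {s!r}")
        npts = bmap[s.wall].size
        i0 = int(round(s.start_frac * (npts - 1)))
        i1 = int(round(s.end_frac * (npts - 1)))
        bmap[s.wall][i0 : i1 + 1] = s.theta_value
    return bmap


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise DivergenceError(name)


def time_step(
    state: FieldState,
    cfg: CaseConfig,
    theta_boundary: dict | None = None,
    dt: float | None = None,
) -> FieldState:
    """One full coupled step of size ``dt`` (default ``cfg.dt``)."""
    p, g = cfg.params, cfg.grid
    if theta_boundary is None:
        theta_boundary = build_theta_boundary(cfg.sources, g)
    if dt is None:
        dt = cfg.dt
    dx1, dx2 = g.dx1, g.dx2

    psi, omega = state.psi, state.omega
    n, theta, phi = state.n, state.theta, state.phi

    # (1) velocity from psi and all explicit source fields, one fused pass
    u, v, S_om, S_th, S_ph = _kernels.coupled_step_fields(
        psi, n, theta, phi, dx1, dx2,
        p.Sc, p.Ra, p.RaT, p.Ran, p.Le, p.r_rho, p.delta_Bm, p.delta_Tm,
    )

    # (2) vorticity with the three buoyancy gradient sources
    omega_new = adi_advance_scalar(
        omega, u, v, TransportCoeffs(p.Sc, 0.0, S_om), dt, g, bc=None
    )
    _check_finite("omega", omega_new)

    # (3) stream function from the new vorticity, (4) wall vorticity
    psi_new = solve_poisson_stream(omega_new, g)
    _check_finite("psi", psi_new)
    apply_wall_vorticity(psi_new, omega_new, g)

    # (5) microorganisms: conservative transport with upward swimming Pe;
    # the flux wall closures are folded into the line solves so the
    # zero-flux balance holds at the new level (exact conservation)
    n_new = adi_advance_scalar(
        n, u, v, TransportCoeffs(1.0, p.Pe, None), dt, g,
        bc=lambda f: apply_micro_bcs(f, p, g, u, v),
        closures=micro_line_closures(p, g, u, v),
    )
    _check_finite("n", n_new)

    # (6) temperature with explicit Brownian / thermophoretic coupling
    zb1 = np.zeros(g.Nx2)
    zb2 = np.zeros(g.Nx1)
    th_closures = (
        (zb1, theta_boundary["left"], zb1, theta_boundary["right"]),
        (zb2, theta_boundary["bottom"], zb2, theta_boundary["top"]),
    )
    theta_new = adi_advance_scalar(
        theta, u, v, TransportCoeffs(p.Le, 0.0, S_th), dt, g,
        bc=lambda f: apply_theta_dirichlet(f, theta_boundary),
        closures=th_closures,
    )
    _check_finite("theta", theta_new)

    # (7) nanoparticles with explicit thermophoretic source dTm * lap(theta)
    phi_new = adi_advance_scalar(
        phi, u, v, TransportCoeffs(p.delta_Bm, 0.0, S_ph), dt, g,
        bc=lambda f: apply_nano_bcs(f, theta_new, p, g, u, v),
        closures=nano_line_closures(theta_new, p, g, u, v),
    )
    _check_finite("phi", phi_new)

    # (8) re-apply every wall condition on the assembled state
    new = FieldState(psi_new, omega_new, n_new, theta_new, phi_new, state.t + dt)
    apply_flux_bcs(new, p, g, theta_boundary)
    return new


def _initial_state(cfg: CaseConfig, initial: FieldState | None) -> FieldState:
    if initial is not None:
        state = initial.copy()
    else:
        state = init_basic_state(cfg.params, cfg.grid)
        if cfg.perturbation_amplitude > 0.0:
            rng = np.random.default_rng(cfg.seed)
            noise = rng.standard_normal(cfg.grid.shape)
            state.omega[1:-1, 1:-1] += cfg.perturbation_amplitude * noise[1:-1, 1:-1]
    return state


def run_to_convergence(
    cfg: CaseConfig,
    initial: FieldState | None = None,
    log_every: int | None = None,
    logger=None,
) -> RunResult:
    """Iterate :func:`time_step` until the steady-state criterion holds.

    Convergence: for every field, ``max_nodes |f^{m+1} - f^m|`` scaled by
    the field's own magnitude ``max(1, max|f^{m+1}|)`` must drop to
    ``epsilon`` or below.  The scaling keeps the criterion meaningful
    across fields of very different size (wall vorticity is a factor
    2/dx2^2 larger than the stream function, so an absolute threshold
    would be dominated by rounding-level psi fluctuations).  On a
    divergence (non-finite field) the step size is halved and the run
    restarts, up to four times.  Deterministic given the configuration.
    """
    bmap = build_theta_boundary(cfg.sources, cfg.grid)
    dt = cfg.dt
    last_err: DivergenceError | None = None
    for _attempt in range(5):
        state = _initial_state(cfg, initial)
        apply_flux_bcs(state, cfg.params, cfg.grid, bmap)
        history: list[float] = []
        try:
            converged = False
            for it in range(1, cfg.max_iters + 1):
                new = time_step(state, cfg, bmap, dt)
                res = 0.0
                for name in FieldState.FIELDS:
                    d = _kernels.max_abs_diff_scaled(
                        getattr(new, name), getattr(state, name)
                    )
                    if d > res:
                        res = d
                history.append(res)
                state = new
                if logger is not None and log_every and it % log_every == 0:
                    from .diagnostics import global_extrema

                    ex = global_extrema(state)
                    logger.info(
                        "iter %d: residual=%.3e psi_max=%.5f phi_max=%.5f",
                        it, res, ex.psi_max, ex.phi_max,
                    )
                if it >= cfg.min_iters and res <= cfg.epsilon:
                    converged = True
                    break
            break
        except DivergenceError as err:
            last_err = err
            dt *= 0.5
            continue
    else:
        raise last_err  # type: ignore[misc]

    from .diagnostics import count_convection_cells, global_extrema

    ex = global_extrema(state)
    diags = {
        "psi_max": ex.psi_max,
        "phi_max": ex.phi_max,
        "n_max": ex.n_max,
        "theta_max": ex.theta_max,
        "cells": count_convection_cells(state.psi, cfg.grid),
        "dt_used": dt,
    }
    return RunResult(
        state=state,
        converged=converged,
        iterations=len(history),
        residual_history=np.asarray(history),
        diagnostics=diags,
    )
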