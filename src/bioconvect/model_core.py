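"""Parameter containers, grid construction, basic states and kinematics.

The solver works in dimensionless variables on the rectangular cavity
``[0, A] x [0, 1]``: x1 is horizontal, x2 vertical, gravity acts along
-x2.  Fields are stored as arrays of shape ``(Nx1, Nx2)`` with index
``(i, j)`` mapping to ``(x1, x2)`` on a node-centred uniform mesh.

Five scalar fields describe one state of the suspension:

* ``psi``   -- stream function (zero on every wall),
* ``omega`` -- vorticity, related to psi by the Poisson equation
  ``lap(psi) = -omega``,
* ``n``     -- microorganism concentration (gravitactic swimmers),
* ``theta`` -- temperature (0 on walls, 1 on thermal sources),
* ``phi``   -- nanoparticle volume fraction.

The dimensionless groups are the bioconvection, thermal and nanoparticle
Rayleigh numbers Ra, RaT, Ran; the Schmidt, Lewis and two Peclet numbers
Sc, Le, Pe, Pen; the Brownian and thermophoretic diffusion parameters
delta_Bm, delta_Tm; and the heat-capacity ratio r_rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

from .errors import InvalidGridError, InvalidInputError

__all__ = [
    "SimulationParams",
    "DimensionalInputs",
    "Grid",
    "FieldState",
    "SourceSpec",
    "dimensionless_groups",
    "make_grid",
    "init_basic_state",
    "velocity_from_stream",
]

WALLS = ("bottom", "top", "left", "right")


@dataclass(frozen=True)
class SimulationParams:
    """Dimensionless groups and physical switches for one run.

    Defaults are the reference operating point of the study: vigorous
    bioconvection (Ra = 1900) competing with natural convection near its
    classical onset (RaT = 1708), unit Schmidt/Lewis/Peclet numbers and a
    small nanoparticle Peclet number so microorganism diffusion dominates
    particle settling.
    """

    Ra: float = 1900.0
    RaT: float = 1708.0
    Ran: float = 0.0
    Sc: float = 1.0
    Le: float = 1.0
    Pe: float = 1.0
    Pen: float = 0.1
    delta_Bm: float = 0.1
    delta_Tm: float = 0.1
    r_rho: float = 2.5
    A: float = 5.0
    Nbar: float = 1.0
    #: Include the printed ``n*Pen`` term in the microorganism wall flux.
    #: Off by default: without it the exponential rest profile is exactly
    #: stationary, which is the self-consistent reading of the model.
    micro_bc_includes_pen: bool = False
    #: Include the settling term ``-Pen*phi`` in the nanoparticle wall
    #: flux.  Off by default: the transport equation carries no settling
    #: advection, so the term makes the wall flux non-zero, total
    #: nanoparticle content drifts indefinitely (the mean mode is
    #: quasi-neutral, decay rate ~Pen^2/delta_Bm) and no steady state is
    #: reachable.  Without it the closure is the classical zero-flux
    #: balance of Brownian diffusion against thermophoresis, consistent
    #: with particles staying dispersed without sedimentation.
    nano_bc_includes_pen: bool = False

    def __post_init__(self) -> None:
        for name in ("Sc", "Le", "delta_Bm", "A", "Nbar"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                raise InvalidInputError(f"{name} must be strictly positive, got {v!r}")
        for name in ("Ra", "RaT", "Ran", "Pe", "Pen", "delta_Tm", "r_rho"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise InvalidInputError(f"{name} must be finite, got {v!r}")

    def replace(self, **kw) -> "SimulationParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class DimensionalInputs:
    """Dimensional quantities (SI) from which the groups are derived.

    Only used for conversion; the solver itself never sees units.
    """

    g: float            # gravity, m/s^2
    nbar: float         # average microorganism count concentration, 1/m^3
    vartheta: float     # microorganism volume, m^3
    delta_rho: float    # rho_m - rho_w, kg/m^3
    rho_w: float        # water density, kg/m^3
    rho_f: float        # base-fluid density, kg/m^3
    rho_p: float        # nanoparticle density, kg/m^3
    nu: float           # kinematic viscosity, m^2/s
    alpha: float        # thermal diffusivity, m^2/s
    beta: float         # thermal expansion coefficient, 1/K
    Dm: float           # microorganism diffusivity, m^2/s
    DB: float           # Brownian diffusivity, m^2/s
    DT: float           # thermophoretic diffusion coefficient, m^2/s
    Th: float           # hot temperature, K
    Tc: float           # cold temperature, K
    TC: float           # reference temperature, K
    phi0: float         # reference nanoparticle volume fraction
    H: float            # cavity height, m
    Vm: float           # upward swimming speed, m/s
    W0: float           # nanoparticle settling speed, m/s
    cp: float           # particle specific heat, J/(kg K)
    cf: float           # fluid specific heat, J/(kg K)

    def __post_init__(self) -> None:
        signed = {"beta", "delta_rho"}
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise InvalidInputError(f"{f.name} must be finite, got {v!r}")
            if f.name not in signed and not v > 0:
                raise InvalidInputError(
                    f"{f.name} must be strictly positive, got {v!r}"
                )
        if self.Th < self.Tc:
            raise InvalidInputError("Th must be >= Tc")


def dimensionless_groups(d: DimensionalInputs) -> SimulationParams:
    """Convert dimensional inputs into the ten dimensionless groups.

    Ra   = g*nbar*vartheta*delta_rho*H^3 / (rho_w*nu*Dm)
    RaT  = g*beta*(Th-Tc)*H^3 / (nu*alpha)
    Ran  = g*(rho_p-rho_f)*phi0*H^3 / (rho_w*nu*alpha)
    Sc   = nu/Dm,  Le = alpha/Dm
    Pe   = Vm*H/Dm,  Pen = W0*H/Dm
    delta_Tm = DT*(Th-Tc) / (Dm*TC*phi0),  delta_Bm = DB/Dm
    r_rho    = rho_p*cp*phi0 / (rho_f*cf)
    """
    H3 = d.H**3
    return SimulationParams(
        Ra=d.g * d.nbar * d.vartheta * d.delta_rho * H3 / (d.rho_w * d.nu * d.Dm),
        RaT=d.g * d.beta * (d.Th - d.Tc) * H3 / (d.nu * d.alpha),
        Ran=d.g * (d.rho_p - d.rho_f) * d.phi0 * H3 / (d.rho_w * d.nu * d.alpha),
        Sc=d.nu / d.Dm,
        Le=d.alpha / d.Dm,
        Pe=d.Vm * d.H / d.Dm,
        Pen=d.W0 * d.H / d.Dm,
        delta_Tm=d.DT * (d.Th - d.Tc) / (d.Dm * d.TC * d.phi0),
        delta_Bm=d.DB / d.Dm,
        r_rho=d.rho_p * d.cp * d.phi0 / (d.rho_f * d.cf),
    )


@dataclass(frozen=True)
class Grid:
    """Uniform node-centred mesh on ``[0, A] x [0, 1]``."""

    Nx1: int
    Nx2: int
    A: float

    @property
    def dx1(self) -> float:
        return self.A / (self.Nx1 - 1)

    @property
    def dx2(self) -> float:
        return 1.0 / (self.Nx2 - 1)

    @property
    def x1(self) -> np.ndarray:
        return np.linspace(0.0, self.A, self.Nx1)

    @property
    def x2(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.Nx2)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.Nx1, self.Nx2)

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinate arrays broadcast to field shape (indexing='ij')."""
        return np.meshgrid(self.x1, self.x2, indexing="ij")


def make_grid(Nx1: int, Nx2: int, A: float) -> Grid:
    """Build a uniform grid; at least 3 nodes are required per direction."""
    if int(Nx1) != Nx1 or int(Nx2) != Nx2 or Nx1 < 3 or Nx2 < 3:
        raise InvalidGridError(
            f"grid needs integer Nx1, Nx2 >= 3, got {Nx1!r} x {Nx2!r}"
        )
    if not A > 0:
        raise InvalidGridError(f"aspect ratio A must be positive, got {A!r}")
    return Grid(int(Nx1), int(Nx2), float(A))


@dataclass
class FieldState:
    """The five coupled scalar fields at one time level."""

    psi: np.ndarray
    omega: np.ndarray
    n: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    t: float = 0.0

    FIELDS = ("psi", "omega", "n", "theta", "phi")

    def copy(self) -> "FieldState":
        return FieldState(
            self.psi.copy(), self.omega.copy(), self.n.copy(),
            self.theta.copy(), self.phi.copy(), self.t,
        )

    def arrays(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.FIELDS}

    def validate(self, grid: Grid) -> None:
        for name, arr in self.arrays().items():
            if arr.shape != grid.shape:
                raise InvalidInputError(
                    f"field '{name}' has shape {arr.shape}, grid is {grid.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"field '{name}' contains non-finite values")


@dataclass(frozen=True)
class SourceSpec:
    """A heated wall segment held at fixed temperature.

    ``start_frac`` / ``end_frac`` are fractions of the wall length
    (bottom/top walls run along x1, side walls along x2).
    """

    wall: str = "bottom"
    start_frac: float = 0.0
    end_frac: float = 0.1
    theta_value: float = 1.0

    def __post_init__(self) -> None:
        from .errors import InvalidSourceError

        if self.wall not in WALLS:
            raise InvalidSourceError(f"wall must be one of {WALLS}, got {self.wall!r}")
        if not (0.0 <= self.start_frac < self.end_frac <= 1.0):
            raise InvalidSourceError(
                "source segment needs 0 <= start_frac < end_frac <= 1, got "
                f"[{self.start_frac}, {self.end_frac}]"
            )

    def to_dict(self) -> dict:
        return {
            "wall": self.wall,
            "start_frac": self.start_frac,
            "end_frac": self.end_frac,
            "theta_value": self.theta_value,
        }


def basic_state_n(x2: np.ndarray, Pe: float, Nbar: float) -> np.ndarray:
    """Rest-state microorganism profile ``Nbar*Pe*exp(Pe*x2)/(exp(Pe)-1)``.

    This is the stationary balance between upward swimming at speed Pe and
    diffusion, normalised so its vertical mean is ``Nbar``.  The Pe -> 0
    limit is the uniform profile ``Nbar``.
    """
    x2 = np.asarray(x2, dtype=float)
    if Pe == 0.0:
        return np.full_like(x2, Nbar)
    return Nbar * Pe * np.exp(Pe * x2) / math.expm1(Pe)


def basic_state_phi(
    x2: np.ndarray, delta_Bm: float, theta_b: np.ndarray | float = 0.0
) -> np.ndarray:
    """Rest-state nanoparticle profile ``-dBm*theta_b + (1-dBm)*x2 + dBm``."""
    x2 = np.asarray(x2, dtype=float)
    return -delta_Bm * np.asarray(theta_b) + (1.0 - delta_Bm) * x2 + delta_Bm


def init_basic_state(p: SimulationParams, g: Grid) -> FieldState:
    """Quiescent initial condition: horizontally uniform rest profiles.

    psi = omega = theta = 0; n and phi take their one-dimensional basic
    states as functions of height.
    """
    nb = basic_state_n(g.x2, p.Pe, p.Nbar)
    phib = basic_state_phi(g.x2, p.delta_Bm)
    shape = g.shape
    return FieldState(
        psi=np.zeros(shape),
        omega=np.zeros(shape),
        n=np.broadcast_to(nb, shape).copy(),
        theta=np.zeros(shape),
        phi=np.broadcast_to(phib, shape).copy(),
        t=0.0,
    )


def interpolate_state(state: FieldState, g_from: Grid, g_to: Grid) -> FieldState:
    """Bilinear transfer of a state onto another grid (same cavity).

    Used to warm-start fine-mesh runs from coarse converged states; the
    receiving run re-applies all wall conditions before stepping.
    """
    from scipy.interpolate import RegularGridInterpolator

    if abs(g_from.A - g_to.A) > 1e-12:
        raise InvalidInputError("grids must share the aspect ratio")
    pts = np.stack(g_to.mesh(), axis=-1)
    out = {}
    for name, arr in state.arrays().items():
        itp = RegularGridInterpolator((g_from.x1, g_from.x2), arr, method="linear")
        out[name] = itp(pts)
    return FieldState(t=state.t, **out)


def velocity_from_stream(psi: np.ndarray, g: Grid) -> tuple[np.ndarray, np.ndarray]:
    """Recover velocity ``u = d(psi)/dx2, v = -d(psi)/dx1``.

    Centred second-order differences in the interior, second-order
    one-sided at the boundary rows.  With this convention the discrete
    interior divergence vanishes identically (mixed centred differences
    commute) and ``omega = dv/dx1 - du/dx2`` satisfies ``lap(psi) = -omega``.
    """
    psi = np.asarray(psi, dtype=float)
    u = np.gradient(psi, g.dx2, axis=1, edge_order=2)
    v = -np.gradient(psi, g.dx1, axis=0, edge_order=2)
    return u, v
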