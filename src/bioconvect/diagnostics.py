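"""Run diagnostics: field extrema, convection-cell counting, nanoparticle
Rayleigh-number sweeps with onset estimation, and the mesh-independence
harness.

A "cell" (roll) is a closed recirculation region of the stream function.
Counting is done by thresholded sign-domain labelling: connected regions
of psi > thr and psi < -thr are counted separately, with the threshold a
fraction of max|psi| so the count is invariant under rescaling psi.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InsufficientDataError, InvalidInputError
from .model_core import FieldState, Grid
from .simulation import CaseConfig, RunResult, run_to_convergence

__all__ = [
    "Extrema",
    "SweepResult",
    "MeshStudyReport",
    "global_extrema",
    "count_convection_cells",
    "sweep_ran",
    "estimate_critical_ran",
    "mesh_independence_study",
]


class Extrema(NamedTuple):
    psi_max: float
    phi_max: float
    n_max: float
    theta_max: float


def global_extrema(state: FieldState) -> Extrema:
    """Field extrema over all nodes.

    ``psi_max`` is the signed stream-function value of largest magnitude
    (so the dominant rotation sense is visible); the other three are
    plain maxima.
    """
    psi = state.psi
    idx = np.unravel_index(np.argmax(np.abs(psi)), psi.shape)
    return Extrema(
        psi_max=float(psi[idx]),
        phi_max=float(np.max(state.phi)),
        n_max=float(np.max(state.n)),
        theta_max=float(np.max(state.theta)),
    )


def count_convection_cells(
    psi: np.ndarray, g: Grid, threshold_frac: float = 0.05
) -> int:
    """Number of distinct convection rolls in a stream-function field.

    Counts connected regions where |psi| exceeds ``threshold_frac`` times
    max|psi|, separately on each sign domain, which merges weak wiggles
    into their parent roll.  Returns 0 for a quiescent field
    (max|psi| < 1e-10).
    """
    if not (0.0 < threshold_frac < 1.0):
        raise InvalidInputError("threshold_frac must lie in (0, 1)")
    psi = np.asarray(psi, dtype=float)
    peak = float(np.max(np.abs(psi)))
    if peak < 1e-10:
        return 0
    thr = threshold_frac * peak
    _, n_pos = ndimage.label(psi > thr)
    _, n_neg = ndimage.label(psi < -thr)
    return int(n_pos + n_neg)


@dataclass
class SweepResult:
    """Diagnostics along an increasing sequence of Ran values."""

    ran_values: np.ndarray
    psi_max: np.ndarray       # magnitude of the stream-function extremum
    phi_max: np.ndarray
    cell_counts: np.ndarray
    converged: np.ndarray
    ran_critical: float | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ran": self.ran_values,
                "psi_max": self.psi_max,
                "phi_max": self.phi_max,
                "cells": self.cell_counts,
                "converged": self.converged,
            }
        )


def sweep_ran(
    base: CaseConfig,
    ran_values: Sequence[float],
    threshold_frac: float = 0.05,
    estimate_onset: bool = True,
) -> SweepResult:
    """Run the solver to steady state at each Ran, warm-starting each run
    from the previous converged state.

    Warm starting follows the physical protocol of slowly increasing the
    nanoparticle load; on the coarse mesh it changes converged answers
    only within the convergence tolerance.
    """
    ran_values = np.asarray(list(ran_values), dtype=float)
    if ran_values.size == 0:
        raise InvalidInputError("ran_values must be nonempty")
    if ran_values.size > 1 and not np.all(np.diff(ran_values) > 0):
        raise InvalidInputError("ran_values must be strictly increasing")

    psi_max = np.empty(ran_values.size)
    phi_max = np.empty(ran_values.size)
    cells = np.empty(ran_values.size, dtype=int)
    conv = np.empty(ran_values.size, dtype=bool)
    prev_state = None
    for k, ran in enumerate(ran_values):
        cfg = base.replace(params=base.params.replace(Ran=float(ran)))
        result = run_to_convergence(cfg, initial=prev_state)
        psi_max[k] = abs(result.diagnostics["psi_max"])
        phi_max[k] = result.diagnostics["phi_max"]
        cells[k] = count_convection_cells(result.state.psi, cfg.grid, threshold_frac)
        conv[k] = result.converged
        if result.converged:
            prev_state = result.state
    sweep = SweepResult(ran_values, psi_max, phi_max, cells, conv)
    if estimate_onset:
        try:
            sweep.ran_critical = estimate_critical_ran(sweep)
        except InsufficientDataError:
            sweep.ran_critical = None
    return sweep


def estimate_critical_ran(
    sweep: SweepResult, slope_factor: float = 5.0
) -> float | None:
    """Onset of instability from the psi_max-vs-Ran curve.

    Returns the midpoint of the first Ran interval whose discrete slope
    is positive and exceeds ``slope_factor`` times the median slope of
    all preceding intervals; ``None`` when the curve never steepens.
    Non-converged points are excluded.  Invariant under uniform rescaling
    of the psi_max values.
    """
    mask = np.asarray(sweep.converged, dtype=bool)
    ran = np.asarray(sweep.ran_values, dtype=float)[mask]
    psi = np.asarray(sweep.psi_max, dtype=float)[mask]
    if ran.size < 3:
        raise InsufficientDataError(
            f"need at least 3 converged sweep points, have {ran.size}"
        )
    slopes = np.diff(psi) / np.diff(ran)
    for k in range(1, slopes.size):
        med = float(np.median(slopes[:k]))
        if slopes[k] > 0.0 and slopes[k] > slope_factor * med:
            return float(0.5 * (ran[k] + ran[k + 1]))
    return None


@dataclass
class MeshStudyReport:
    """Converged extrema per mesh per probed Ran value."""

    meshes: list[Grid]
    probe_ran: np.ndarray
    psi_max: np.ndarray        # shape (n_mesh, n_probe)
    phi_max: np.ndarray        # shape (n_mesh, n_probe)
    converged: np.ndarray      # shape (n_mesh, n_probe)
    rel_diff: np.ndarray       # max relative difference to the finest mesh
    selected: int              # index of the selected (coarsest adequate) mesh

    def to_dataframe(self) -> pd.DataFrame:
        rows = {}
        rows["mesh"] = [f"{g.Nx1}x{g.Nx2}" for g in self.meshes]
        for j, ran in enumerate(self.probe_ran):
            rows[f"phi_max_ran={ran:g}"] = self.phi_max[:, j]
            rows[f"psi_max_ran={ran:g}"] = self.psi_max[:, j]
        rows["rel_diff_to_finest"] = self.rel_diff
        return pd.DataFrame(rows)


def mesh_independence_study(
    base: CaseConfig,
    meshes: Sequence[Grid],
    probe_ran: Sequence[float],
    initial: "FieldState | None" = None,
) -> MeshStudyReport:
    """Converged diagnostics on a ladder of meshes at a few Ran probes.

    The selected mesh is the coarsest whose psi_max and phi_max differ
    from the finest mesh by less than 0.5% relatively at every probe.

    Runs are chained: each mesh warm-starts from the previous (coarser)
    mesh's converged state, bilinearly interpolated, and each probe from
    the previous probe on the same mesh.  The common history makes the
    inter-mesh comparison a pure discretisation comparison (and finer
    meshes converge in a small fraction of a cold run's iterations).
    ``initial`` optionally seeds the first (coarsest) mesh.
    """
    from .model_core import interpolate_state

    meshes = list(meshes)
    if len(meshes) < 2:
        raise InvalidInputError("mesh study needs at least 2 meshes")
    probe_ran = np.asarray(list(probe_ran), dtype=float)
    if probe_ran.size == 0:
        raise InvalidInputError("probe_ran must be nonempty")

    order = np.argsort([g.Nx1 * g.Nx2 for g in meshes], kind="stable")
    n_mesh, n_probe = len(meshes), probe_ran.size
    psi_max = np.empty((n_mesh, n_probe))
    phi_max = np.empty((n_mesh, n_probe))
    conv = np.empty((n_mesh, n_probe), dtype=bool)
    carry = initial  # state on the previous (coarser) mesh
    carry_grid = meshes[order[0]] if initial is not None else None
    for mi in order:
        mesh = meshes[mi]
        cfg_mesh = base.replace(grid=mesh)
        prev = (
            interpolate_state(carry, carry_grid, mesh)
            if carry is not None and carry_grid is not None
            else carry
        )
        first_on_mesh = None
        for pj, ran in enumerate(probe_ran):
            cfg = cfg_mesh.replace(params=base.params.replace(Ran=float(ran)))
            result = run_to_convergence(cfg, initial=prev)
            psi_max[mi, pj] = abs(result.diagnostics["psi_max"])
            phi_max[mi, pj] = result.diagnostics["phi_max"]
            conv[mi, pj] = result.converged
            if result.converged:
                prev = result.state
                if first_on_mesh is None:
                    first_on_mesh = result.state
        if first_on_mesh is not None:
            carry, carry_grid = first_on_mesh, mesh

    finest = int(np.argmax([g.Nx1 * g.Nx2 for g in meshes]))
    denom_psi = np.where(np.abs(psi_max[finest]) > 0, np.abs(psi_max[finest]), 1.0)
    denom_phi = np.where(np.abs(phi_max[finest]) > 0, np.abs(phi_max[finest]), 1.0)
    rel = np.maximum(
        np.max(np.abs(psi_max - psi_max[finest]) / denom_psi, axis=1),
        np.max(np.abs(phi_max - phi_max[finest]) / denom_phi, axis=1),
    )
    order = np.argsort([g.Nx1 * g.Nx2 for g in meshes], kind="stable")
    selected = finest
    for mi in order:
        if rel[mi] < 0.005:
            selected = int(mi)
            break
    return MeshStudyReport(
        meshes=meshes,
        probe_ran=probe_ran,
        psi_max=psi_max,
        phi_max=phi_max,
        converged=conv,
        rel_diff=rel,
        selected=selected,
    )
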