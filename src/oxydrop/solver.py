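"""Conservative finite-volume integration of the axisymmetric droplet model.

The dimensionless system on the disc r in [0, R_tilde]:

    d(c_oxy)/dt  = (1/r) d/dr ( r d(c_oxy)/dr ) - s(c_oxy) c_cell c_oxy/(K + c_oxy)
    d(c_cell)/dt = (1/r) d/dr [ r ( Dcell s d(c_cell)/dr - chi s c_cell d f/dr ) ]

with s the unit-amplitude tanh motility switch, f = c/(K_chi + c) the
aerotactic sensing function, a Robin oxygen influx d(c_oxy)/dr = kt_tilde
(1 - c_oxy) at the rim, zero total cell flux at both faces, and symmetry at
r = 0 (handled by the face-flux formulation; nothing is ever evaluated at
r = 0).  Both fields start uniform at 1: cells dispersed at ccell_0 and
oxygen air-saturated, since suspensions are prepared aerobically.

The solver is deterministic; there are no stochastic elements or seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import DimensionlessParams

__all__ = [
    "RadialGrid",
    "FieldState",
    "Trajectory",
    "build_grid",
    "initial_state",
    "advance",
    "simulate",
    "steady_disc_oracle",
]


@dataclass(frozen=True)
class RadialGrid:
    """Uniform cell-centered finite-volume grid on [0, R_tilde]."""

    R_tilde: float
    N: int
    h: float
    centers: np.ndarray
    faces: np.ndarray

    def volumes(self) -> np.ndarray:
        """Control-volume areas 2*pi*r_i*h (exact for the uniform grid)."""
        return 2.0 * math.pi * self.centers * self.h


def build_grid(R_tilde: float, N: int) -> RadialGrid:
    """Build the radial grid; first face at 0, last at R_tilde."""
    if N < 16:
        raise ValueError(f"need at least 16 control volumes, got {N}")
    if not R_tilde > 0:
        raise ValueError("R_tilde must be positive")
    h = R_tilde / N
    faces = np.linspace(0.0, R_tilde, N + 1)
    centers = 0.5 * (faces[:-1] + faces[1:])
    return RadialGrid(R_tilde=R_tilde, N=N, h=h, centers=centers, faces=faces)


@dataclass
class FieldState:
    """Radial profiles at one instant (oxygen scaled by cO2_sat, cells by ccell_0)."""

    t: float
    c_oxy: np.ndarray
    c_cell: np.ndarray


def initial_state(grid: RadialGrid) -> FieldState:
    """Uniformly dispersed cells in air-saturated liquid: both fields = 1."""
    return FieldState(
        t=0.0,
        c_oxy=np.ones(grid.N),
        c_cell=np.ones(grid.N),
    )


@dataclass
class Trajectory:
    """Field time series at a fixed output cadence plus solver diagnostics.

    ``diagnostics`` keys: n_steps, status ('t_max'|'steady'|'anoxia'|'vanish'),
    t_form / t_vanish / steady_time (NaN if the event never occurred, tracked
    per step, not per output sample), min_oxy (global min over space and
    time), mass_rel_drift (relative cell-content change over the run).
    """

    grid: RadialGrid
    params: DimensionlessParams
    times: np.ndarray
    c_oxy: np.ndarray
    c_cell: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return len(self.times)

    def state(self, i: int) -> FieldState:
        return FieldState(t=self.times[i], c_oxy=self.c_oxy[i], c_cell=self.c_cell[i])

    def states(self):
        for i in range(self.n_states):
            yield self.state(i)

    def save(self, path) -> None:
        """Persist grid, parameters, field series and diagnostics to HDF5."""
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("times", data=self.times)
            f.create_dataset("c_oxy", data=self.c_oxy)
            f.create_dataset("c_cell", data=self.c_cell)
            g = f.create_group("grid")
            g.attrs["R_tilde"] = self.grid.R_tilde
            g.attrs["N"] = self.grid.N
            p = f.create_group("params")
            for k in (
                "R_tilde", "kt_tilde", "Dcell_tilde", "chi_tilde",
                "K_tilde", "K_chi_tilde", "c_crit_tilde", "delta_tilde",
                "l_O2", "tau",
            ):
                p.attrs[k] = getattr(self.params, k)
            d = f.create_group("diagnostics")
            for k, v in self.diagnostics.items():
                d.attrs[k] = v

    @classmethod
    def load(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as f:
            grid = build_grid(float(f["grid"].attrs["R_tilde"]), int(f["grid"].attrs["N"]))
            params = DimensionlessParams(**{k: float(v) for k, v in f["params"].attrs.items()})
            return cls(
                grid=grid,
                params=params,
                times=f["times"][:],
                c_oxy=f["c_oxy"][:],
                c_cell=f["c_cell"][:],
                diagnostics={k: v for k, v in f["diagnostics"].attrs.items()},
            )


_STATUS_NAMES = {
    _kernels.STATUS_TMAX: "t_max",
    _kernels.STATUS_STEADY: "steady",
    _kernels.STATUS_ANOXIA: "anoxia",
    _kernels.STATUS_VANISH: "vanish",
    _kernels.STATUS_FAILED: "failed",
}

_UPTAKE_MODES = {"full": _kernels.UPTAKE_FULL, "none": _kernels.UPTAKE_NONE}


def simulate(
    params: DimensionlessParams,
    grid: RadialGrid,
    t_max: float,
    cadence: float = 0.5,
    *,
    initial: FieldState | None = None,
    uptake: str | float = "full",
    evolve_cells: bool = True,
    dt_max: float = 5e-3,
    cfl: float = 0.4,
    steady_tol: float = 1e-6,
    steady_span: float = 1.0,
    stop_on_anoxia: bool = False,
    stop_on_vanish: bool = False,
) -> Trajectory:
    """Integrate the model and return the sampled trajectory.

    ``uptake`` is ``"full"`` (the model's switched Michaelis-Menten sink),
    ``"none"``, or a float Q for a constant volumetric sink (verification
    runs).  The run stops early once the steady-state criterion (max field
    rate below ``steady_tol`` sustained over ``steady_span`` time units) is
    met, or on first anoxia / core vanishing when requested.
    """
    if not t_max > 0:
        raise ValueError("t_max must be positive")
    if grid.R_tilde != params.R_tilde:
        raise ValueError(
            f"grid radius {grid.R_tilde} does not match params.R_tilde {params.R_tilde}"
        )
    state = initial_state(grid) if initial is None else initial
    c_oxy = np.array(state.c_oxy, dtype=float, copy=True)
    c_cell = np.array(state.c_cell, dtype=float, copy=True)
    if c_oxy.shape != (grid.N,) or c_cell.shape != (grid.N,):
        raise ValueError("initial fields must match the grid")
    if np.any(c_oxy < 0) or np.any(c_oxy > 1 + 1e-9) or np.any(c_cell < -1e-12):
        raise ValueError("initial fields violate bounds (0<=c_oxy<=1, c_cell>=0)")

    if isinstance(uptake, str):
        mode, amp = _UPTAKE_MODES[uptake], 1.0
    else:
        mode, amp = _kernels.UPTAKE_CONST, float(uptake)

    n_out_max = int(math.ceil(t_max / cadence)) + 3
    out_times = np.empty(n_out_max)
    out_oxy = np.empty((n_out_max, grid.N))
    out_cell = np.empty((n_out_max, grid.N))

    mass0 = float(np.sum(c_cell * grid.centers) * grid.h)

    (n_out, n_steps, t_end, t_form, t_vanish, min_oxy, steady_time, status) = (
        _kernels.integrate(
            c_oxy,
            c_cell,
            grid.centers,
            grid.faces,
            grid.h,
            params.kt_inv,
            params.Dcell_tilde,
            params.chi_tilde,
            params.K_tilde,
            params.K_chi_tilde,
            params.c_crit_tilde,
            params.delta_tilde,
            mode,
            amp,
            evolve_cells,
            t_max,
            dt_max,
            cfl,
            steady_tol,
            steady_span,
            stop_on_anoxia,
            stop_on_vanish,
            cadence,
            out_times,
            out_oxy,
            out_cell,
        )
    )
    if status == _kernels.STATUS_FAILED:
        raise RuntimeError(
            f"solver failure at t={t_end:.6g} after {n_steps} steps "
            "(non-finite field or unrecoverable positivity violation)"
        )
    mass_end = float(np.sum(c_cell * grid.centers) * grid.h)
    diagnostics = {
        "n_steps": int(n_steps),
        "status": _STATUS_NAMES[status],
        "t_end": float(t_end),
        "t_form": float(t_form) if t_form >= 0 else math.nan,
        "t_vanish": float(t_vanish) if t_vanish >= 0 else math.nan,
        "steady_time": float(steady_time) if steady_time >= 0 else math.nan,
        "min_oxy": float(min_oxy),
        "mass_rel_drift": abs(mass_end - mass0) / mass0 if evolve_cells else 0.0,
    }
    return Trajectory(
        grid=grid,
        params=params,
        times=out_times[:n_out].copy(),
        c_oxy=out_oxy[:n_out].copy(),
        c_cell=out_cell[:n_out].copy(),
        diagnostics=diagnostics,
    )


def advance(
    state: FieldState,
    params: DimensionlessParams,
    grid: RadialGrid,
    dt: float,
    **kwargs,
) -> FieldState:
    """Advance a state by dt (internally substepping per the stability policy)."""
    traj = simulate(
        params,
        grid,
        t_max=dt,
        cadence=dt,
        initial=state,
        steady_tol=0.0,  # never stop early on steadiness within a single advance
        **kwargs,
    )
    final = traj.state(traj.n_states - 1)
    final.t = state.t + dt
    return final


def steady_disc_oracle(Q: float, c_edge: float, grid: RadialGrid) -> np.ndarray:
    """Closed-form steady profile for a constant volumetric sink on the disc.

    Solves (1/r)(r c')' = Q with c(R_tilde) = c_edge:
    c(r) = c_edge - Q (R_tilde^2 - r^2) / 4, evaluated at cell centers.
    """
    if Q < 0:
        raise ValueError("Q must be non-negative")
    return c_edge - Q * (grid.R_tilde**2 - grid.centers**2) / 4.0
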