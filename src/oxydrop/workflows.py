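"""High-level reproduction analyses built from the library primitives.

These are the computations the numbered analysis scripts, the test suite
and the acceptance script share: the three reference droplet conditions,
the plateau annulus width, the transient-core lifetime, the state-diagram
boundaries, and the uptake-rate recovery from the annulus-width scaling.
Everything is deterministic.
"""

from __future__ import annotations

import math

import numpy as np

from .model import DimensionlessParams, load_preset, peclet
from .observables import classification_horizon, classify_regime, core_trace, total_cells
from .solver import Trajectory, build_grid, simulate
from .state_diagram import (
    SolverConfig,
    annulus_scaling,
    fit_boundary_linear,
    onset_boundary,
    permanence_boundary,
)

__all__ = [
    "run_condition",
    "plateau_annulus_width",
    "transient_lifetime",
    "cell_conservation",
    "onset_radius",
    "permanence_prefactor",
    "recover_uptake_rate",
    "peclet_estimate",
    "CAPTION_CONDITIONS",
]

#: The three reference (R_tilde, kt_inv) droplet conditions: small dilute,
#: large concentrated, small concentrated.
CAPTION_CONDITIONS = {
    "small_dilute": (0.96, 2.8),
    "large_concentrated": (9.3, 0.7),
    "small_concentrated": (2.7, 1.0),
}


def run_condition(
    R_tilde: float,
    kt_inv: float,
    N: int = 512,
    t_max: float | None = None,
    stop_on_vanish: bool = True,
    **overrides,
) -> Trajectory:
    """Integrate one (R_tilde, kt_inv) condition to its classification horizon."""
    params = DimensionlessParams.from_ratios(R_tilde, kt_inv, **overrides)
    grid = build_grid(R_tilde, N)
    if t_max is None:
        t_max = classification_horizon(R_tilde)
    return simulate(params, grid, t_max=t_max, cadence=0.5, stop_on_vanish=stop_on_vanish)


def plateau_annulus_width(traj: Trajectory, window: float | None = None) -> float:
    """Post-formation plateau of the annulus width (dimensionless).

    The interface recedes in quantized grid-cell hops that become ever
    rarer; the plateau is declared at the earliest post-formation time
    from which the core radius moves by no more than one grid spacing over
    one droplet-scale diffusion time R_tilde**2 (the erosion timescale).
    Returns the mean annulus width over that quiescent window.
    """
    trace = core_trace(traj)
    if not trace.formed:
        raise ValueError("no core formed; annulus width undefined")
    if window is None:
        window = traj.grid.R_tilde**2
    t = trace.times
    r = trace.r_core
    h = traj.grid.h
    i0 = int(np.argmax(r))  # search from maximal core extent onward
    for i in range(i0, len(t)):
        in_win = (t >= t[i]) & (t <= t[i] + window)
        if t[-1] < t[i] + window:
            break
        if np.max(np.abs(r[in_win] - r[i])) <= h + 1e-12:
            return float(np.mean(trace.ell[in_win]))
    # no fully quiescent window inside the run: fall back to the final window
    in_win = t >= t[-1] - window
    return float(np.mean(trace.ell[in_win]))


def transient_lifetime(traj: Trajectory) -> float:
    """Dimensionless time from start until the anoxic core has vanished."""
    trace = core_trace(traj)
    if not trace.vanished:
        raise ValueError("core never vanished in this run")
    return float(trace.t_vanish)


def cell_conservation(traj: Trajectory) -> float:
    """Relative change of total cell content between t=0 and core vanishing
    (or the end of the run if no vanishing occurred)."""
    trace = core_trace(traj)
    k = traj.n_states - 1
    if trace.vanished:
        k = int(np.argmin(np.abs(traj.times - trace.t_vanish)))
    m0 = total_cells(traj.state(0), traj.grid)
    m1 = total_cells(traj.state(k), traj.grid)
    return abs(m1 - m0) / m0


def onset_radius(
    kt_inv: float = 0.7,
    N: int = 192,
    bracket=(0.5, 2.0),
    tol: float = 0.1,
) -> float:
    """Critical R_tilde for first anoxia at the given kt_inv, by bisection."""
    config = SolverConfig(N=N)
    try:
        r_star, _ = onset_boundary(kt_inv, config, bracket=bracket, tol=tol)
    except ValueError:
        # bracket missed the boundary: widen geometrically once
        r_star, _ = onset_boundary(
            kt_inv, config, bracket=(bracket[0] / 2, bracket[1] * 2), tol=tol
        )
    return r_star


_PERMANENCE_BRACKETS = {2.0: (1.2, 2.5), 4.0: (0.8, 1.5)}


def permanence_prefactor(
    kt_inv_values=(2.0, 4.0),
    N: int = 256,
    tol: float = 0.25,
    brackets: dict | None = None,
):
    """Origin-constrained prefactor a of the permanence boundary R = a*kt.

    Bisects the transient/permanent classification at each kt_inv and fits
    R_dagger = a / kt_inv through the origin.  Returns (a, boundary points).
    """
    brackets = dict(_PERMANENCE_BRACKETS) if brackets is None else brackets
    config = SolverConfig(N=N)
    points = []
    for kt_inv in kt_inv_values:
        bracket = brackets.get(kt_inv, (0.8, 4.0))
        try:
            r_dag, _ = permanence_boundary(kt_inv, config, bracket=bracket, tol=tol)
        except ValueError:
            r_dag, _ = permanence_boundary(
                kt_inv, config, bracket=(bracket[0] / 2, bracket[1] * 2), tol=tol
            )
        points.append((kt_inv, r_dag))
    return fit_boundary_linear(points), points


def recover_uptake_rate(
    ccell_0_per_mL=(1e10, 2e10, 4e10, 8e10),
    preset: str = "bmb-minimal",
    N: int = 512,
    kt_inv: float = 0.7,
):
    """Fit the penetration-length law to simulated initial annulus widths.

    Runs the named preset at each cell concentration (given per mL),
    extracts ell_init, and recovers the per-cell uptake rate kO2 in
    molecules s⁻¹ cell⁻¹.  Returns (table, fit dict).
    """
    base = load_preset(preset)
    c_um3 = [c / 1e12 for c in ccell_0_per_mL]  # cells/mL -> cells/μm³
    return annulus_scaling(c_um3, base, SolverConfig(N=N), kt_inv=kt_inv)


def peclet_estimate(vc: float = 0.05, L: float = 3.5e3, DO2: float = 2.0e3) -> float:
    """Péclet number of evaporation-driven convection at the largest droplet."""
    return peclet(vc, L, DO2)


def restore_minutes(t_tilde: float, R_um: float, R_tilde: float, DO2: float = 2.0e3) -> float:
    """Convert dimensionless time to minutes via tau = (R/R_tilde)^2 / DO2."""
    l_O2 = R_um / R_tilde
    return t_tilde * (l_O2**2 / DO2) / 60.0


def restore_micrometers(length_tilde: float, R_um: float, R_tilde: float) -> float:
    """Convert a dimensionless length to μm via l_O2 = R/R_tilde."""
    return length_tilde * R_um / R_tilde
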