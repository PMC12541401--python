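"""Measured quantities extracted from trajectories.

The anoxic core is the contiguous central region where oxygen sits below
the motility-loss threshold ``c_crit`` (the same threshold that switches
motility and uptake off, since the core is defined by both anoxia and
motility loss).  The motile annulus is everything outside it; its width
``ell = R - r_core`` is the primary observable, together with the total
oxygen content of the annulus and the three-way regime classification
(aerobic / transient anoxia / permanent anoxia).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .solver import FieldState, RadialGrid, Trajectory

__all__ = [
    "CoreTrace",
    "RegimeLabel",
    "core_radius",
    "core_radius_profile",
    "core_trace",
    "total_oxygen",
    "total_cells",
    "classify_regime",
    "classification_horizon",
    "kymograph",
]


@dataclass
class CoreTrace:
    """Anoxic-core radius and annulus width versus time (dimensionless).

    ``ell_init`` is the annulus width at maximal core extent during the
    run (the minimum annulus width); NaN if a core never forms.
    ``t_form`` / ``t_vanish`` are NaN when the event never occurred.
    """

    times: np.ndarray
    r_core: np.ndarray
    ell: np.ndarray
    R_tilde: float
    ell_init: float
    t_form: float
    t_vanish: float

    @property
    def formed(self) -> bool:
        return not math.isnan(self.t_form)

    @property
    def vanished(self) -> bool:
        return not math.isnan(self.t_vanish)


@dataclass
class RegimeLabel:
    """Three-way morphological classification plus diagnostics."""

    label: str  # aerobic | transient_anoxia | permanent_anoxia | indeterminate
    t_form: float
    t_vanish: float
    r_core_end: float
    steady: bool
    t_end: float


def core_radius_profile(c_oxy: np.ndarray, r_centers: np.ndarray, R: float, threshold: float) -> float:
    """Outer radius of the contiguous central sub-threshold region.

    Works on any radial profile (simulated or recovered from images).
    Returns 0 when the innermost bin is above threshold; the threshold
    crossing is located by linear interpolation between adjacent centers.
    """
    anoxic = c_oxy < threshold
    if not anoxic[0]:
        return 0.0
    above = np.nonzero(~anoxic)[0]
    if len(above) == 0:
        return float(R)
    j = int(above[0])  # first aerobic bin; crossing lies in (r[j-1], r[j])
    c0, c1 = c_oxy[j - 1], c_oxy[j]
    frac = (threshold - c0) / (c1 - c0) if c1 > c0 else 0.5
    r = r_centers[j - 1] + frac * (r_centers[j] - r_centers[j - 1])
    return float(min(max(r, 0.0), R))


def core_radius(state: FieldState, grid: RadialGrid, c_crit_tilde: float) -> float:
    """Anoxic-core radius of a single solver state."""
    return core_radius_profile(state.c_oxy, grid.centers, grid.R_tilde, c_crit_tilde)


def core_trace(traj: Trajectory) -> CoreTrace:
    """Core radius, annulus width and the formation/vanishing times.

    Event times come from the per-step solver diagnostics when available
    (more precise than the output cadence); ``ell_init`` is measured at the
    time of maximal core extent.
    """
    if traj.n_states < 2:
        raise ValueError("need a trajectory with at least 2 states")
    ccrit = traj.params.c_crit_tilde
    R = traj.grid.R_tilde
    r_core = np.array(
        [core_radius_profile(c, traj.grid.centers, R, ccrit) for c in traj.c_oxy]
    )
    ell = R - r_core
    formed_any = bool(np.any(r_core > 0))
    t_form = traj.diagnostics.get("t_form", math.nan)
    t_vanish = traj.diagnostics.get("t_vanish", math.nan)
    if math.isnan(t_form) and formed_any:
        t_form = float(traj.times[np.nonzero(r_core > 0)[0][0]])
    if math.isnan(t_vanish) and formed_any:
        i0 = np.nonzero(r_core > 0)[0][0]
        gone = np.nonzero(r_core[i0:] == 0.0)[0]
        if len(gone):
            t_vanish = float(traj.times[i0 + gone[0]])
    ell_init = float(ell[np.argmax(r_core)]) if formed_any else math.nan
    return CoreTrace(
        times=traj.times.copy(),
        r_core=r_core,
        ell=ell,
        R_tilde=R,
        ell_init=ell_init,
        t_form=t_form,
        t_vanish=t_vanish,
    )


def total_oxygen(traj: Trajectory, trace: CoreTrace | None = None) -> np.ndarray:
    """Oxygen content of the motile annulus, normalized by its saturation value.

    Per state: integral of c_oxy r dr over [r_core, R] divided by the same
    integral of 1 (the saturated annulus).  Values lie in [0, 1]; a fully
    anoxic state (empty annulus) contributes 0.
    """
    if trace is None:
        trace = core_trace(traj)
    rc = traj.grid.centers
    h = traj.grid.h
    out = np.empty(traj.n_states)
    for k in range(traj.n_states):
        mask = rc >= trace.r_core[k]
        denom = float(np.sum(rc[mask]) * h)
        out[k] = float(np.sum(traj.c_oxy[k][mask] * rc[mask]) * h) / denom if denom > 0 else 0.0
    return out


def total_cells(state: FieldState, grid: RadialGrid) -> float:
    """Dimensionless cell content 2*pi*sum(c_cell r h); pi*R_tilde^2 initially."""
    return float(2.0 * math.pi * np.sum(state.c_cell * grid.centers) * grid.h)


def classification_horizon(R_tilde: float, base: float = 100.0, scale: float = 30.0) -> float:
    """Integration horizon before a persistent core is declared permanent.

    Core erosion operates on a multiple of the droplet-scale diffusion time
    R_tilde^2; the default multiple (30) comfortably exceeds the measured
    erosion time of the transient reference condition (~20 R_tilde^2).
    """
    return max(base, scale * R_tilde * R_tilde)


def classify_regime(traj: Trajectory, horizon: float | None = None) -> RegimeLabel:
    """Three-way regime label.

    aerobic: no anoxic region ever formed (run steady or past the horizon);
    transient_anoxia: a core formed and vanished;
    permanent_anoxia: a core formed and persists, with the run either at
    the steady-state criterion or past the horizon;
    indeterminate: the run stopped too early to decide (signals that t_max
    must be raised).
    """
    if horizon is None:
        horizon = classification_horizon(traj.params.R_tilde)
    trace = core_trace(traj)
    steady = traj.diagnostics.get("status") == "steady"
    t_end = float(traj.diagnostics.get("t_end", traj.times[-1]))
    r_end = float(trace.r_core[-1])
    ran_out = t_end >= horizon - 1e-9
    if not trace.formed:
        label = "aerobic" if (steady or ran_out) else "indeterminate"
    elif trace.vanished:
        label = "transient_anoxia"
    elif r_end > 0 and (steady or ran_out):
        label = "permanent_anoxia"
    else:
        label = "indeterminate"
    return RegimeLabel(
        label=label,
        t_form=trace.t_form,
        t_vanish=trace.t_vanish,
        r_core_end=r_end,
        steady=steady,
        t_end=t_end,
    )


def kymograph(traj: Trajectory, field: str = "c_cell"):
    """Space-time matrix of a field (rows: radius, columns: time).

    The cell field is normalized by its initial spatially uniform value,
    so a uniform aerobic run yields an all-ones kymograph.
    """
    if field not in ("c_cell", "c_oxy"):
        raise ValueError("field must be 'c_cell' or 'c_oxy'")
    data = getattr(traj, field).T.copy()
    if field == "c_cell":
        c0 = float(np.mean(traj.c_cell[0]))
        data /= c0
    return traj.grid.centers.copy(), traj.times.copy(), data


def kymograph_frame(traj: Trajectory, field: str = "c_cell"):
    """Kymograph as a pandas DataFrame (radius index, time columns)."""
    import pandas as pd

    r, t, data = kymograph(traj, field)
    df = pd.DataFrame(data, index=pd.Index(r, name="r_tilde"),
                      columns=pd.Index(np.round(t, 6), name="t_tilde"))
    return df
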