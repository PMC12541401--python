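"""Parameter sweeps, phase-boundary bisection, and boundary/scaling fits.

The morphological state diagram lives in the plane of the reduced droplet
radius R_tilde and the reduced diffusion-to-influx ratio kt_inv.  Two
boundaries are located by bisection on full simulations: the onset of
anoxia (does oxygen anywhere ever drop below c_crit?) and the
transient/permanent boundary of core formation.  Two functional forms are
fitted to the latter: a line through the origin in kt (R = a/kt_inv, the
saturation-free regime) and the saturating form R = A/(B + C*kt_inv).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import DimensionlessParams, MOLECULES_PER_UM3_PER_UM, PhysicalParams, nondimensionalize
from .observables import classification_horizon, classify_regime, core_trace, RegimeLabel
from .solver import build_grid, simulate

__all__ = [
    "SolverConfig",
    "SweepResult",
    "BoundaryFit",
    "classify_point",
    "sweep",
    "onset_boundary",
    "permanence_boundary",
    "fit_boundary_linear",
    "fit_boundary_saturating",
    "annulus_scaling",
]

_LABEL_ORDER = {"aerobic": 0, "transient_anoxia": 1, "permanent_anoxia": 2}


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings shared by sweep and boundary runs."""

    N: int = 256
    cadence: float = 2.0
    dt_max: float = 5e-3
    horizon_base: float = 100.0
    horizon_scale: float = 30.0
    horizon_cap: float = math.inf  # bound sweep cost far from the boundary
    ratio_overrides: dict = field(default_factory=dict)

    def horizon(self, R_tilde: float) -> float:
        h = classification_horizon(R_tilde, self.horizon_base, self.horizon_scale)
        return min(h, self.horizon_cap)

    def params(self, R_tilde: float, kt_inv: float) -> DimensionlessParams:
        return DimensionlessParams.from_ratios(R_tilde, kt_inv, **self.ratio_overrides)


@dataclass
class SweepResult:
    """Classification of every (R_tilde, kt_inv) grid point."""

    points: list  # of (R_tilde, kt_inv, RegimeLabel)
    monotone_ok: bool
    violations: list

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "R_tilde": r,
                    "kt_inv": k,
                    "label": lab.label,
                    "t_form": lab.t_form,
                    "t_vanish": lab.t_vanish,
                    "r_core_end": lab.r_core_end,
                }
                for r, k, lab in self.points
            ]
        )


@dataclass
class BoundaryFit:
    """Fitted boundary coefficients with identifiable ratios and residuals."""

    form: str
    coefficients: dict
    residuals: np.ndarray
    points: list


def classify_point(
    R_tilde: float,
    kt_inv: float,
    config: SolverConfig = SolverConfig(),
    horizon: float | None = None,
) -> RegimeLabel:
    """Classify one point of the diagram by a full simulation.

    The run stops early on core vanishing (transient confirmed) or on the
    steady-state criterion; otherwise it integrates to the classification
    horizon before a persistent core counts as permanent.
    """
    if horizon is None:
        horizon = config.horizon(R_tilde)
    params = config.params(R_tilde, kt_inv)
    grid = build_grid(R_tilde, config.N)
    traj = simulate(
        params,
        grid,
        t_max=horizon,
        cadence=config.cadence,
        dt_max=config.dt_max,
        stop_on_vanish=True,
    )
    return classify_regime(traj, horizon=horizon)


def sweep(
    R_tilde_list,
    kt_inv_list,
    config: SolverConfig = SolverConfig(),
) -> SweepResult:
    """Classify a full (R_tilde, kt_inv) grid.

    Failures are recorded as 'indeterminate' labels rather than dropped.
    The expected ordering aerobic -> transient -> permanent along
    increasing R_tilde is checked at every kt_inv and any violation
    recorded.
    """
    R_tilde_list = list(R_tilde_list)
    kt_inv_list = list(kt_inv_list)
    if not R_tilde_list or not kt_inv_list:
        raise ValueError("parameter lists must be nonempty")
    points = []
    for kt_inv in kt_inv_list:
        for R_tilde in R_tilde_list:
            points.append((R_tilde, kt_inv, classify_point(R_tilde, kt_inv, config)))
    violations = []
    for kt_inv in kt_inv_list:
        col = sorted(
            [(r, lab.label) for r, k, lab in points if k == kt_inv and lab.label in _LABEL_ORDER]
        )
        ranks = [_LABEL_ORDER[lab] for _, lab in col]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            violations.append((kt_inv, col))
    return SweepResult(points=points, monotone_ok=not violations, violations=violations)


def _bisect(predicate, lo: float, hi: float, tol: float):
    """Standard bisection: predicate False at lo, True at hi."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi), (lo, hi)


def onset_boundary(
    kt_inv: float,
    config: SolverConfig = SolverConfig(),
    bracket=(0.5, 2.0),
    tol: float = 0.1,
    probe=None,
):
    """Critical R_tilde at which an anoxic region first appears.

    The probe asks whether min over space and time of oxygen drops below
    c_crit; each probe run stops at first anoxia or at steadiness.
    Returns (R_tilde_star, (lo, hi) final bracket).
    """

    def default_probe(R_tilde: float) -> bool:
        params = config.params(R_tilde, kt_inv)
        grid = build_grid(R_tilde, config.N)
        traj = simulate(
            params,
            grid,
            t_max=config.horizon(R_tilde),
            cadence=config.cadence,
            dt_max=min(config.dt_max, 1e-3),  # resolve the early depletion transient
            stop_on_anoxia=True,
        )
        return traj.diagnostics["min_oxy"] < params.c_crit_tilde

    probe = probe or default_probe
    lo, hi = bracket
    if probe(lo):
        raise ValueError(f"bracket low end R_tilde={lo} is already anoxic; widen the search")
    if not probe(hi):
        raise ValueError(f"bracket high end R_tilde={hi} is still aerobic; widen the search")
    return _bisect(probe, lo, hi, tol)


def permanence_boundary(
    kt_inv: float,
    config: SolverConfig = SolverConfig(),
    bracket=(1.0, 4.0),
    tol: float = 0.25,
    probe=None,
):
    """R_tilde separating transient from permanent core formation.

    The probe is the full three-way classification; 'permanent_anoxia'
    counts as above the boundary, aerobic or transient as below.
    Returns (R_tilde_dagger, (lo, hi) final bracket).
    """

    def default_probe(R_tilde: float) -> bool:
        label = classify_point(R_tilde, kt_inv, config)
        if label.label == "indeterminate":
            raise RuntimeError(
                f"indeterminate classification at R_tilde={R_tilde}, kt_inv={kt_inv} "
                f"(t_max={config.horizon(R_tilde)}); raise the horizon"
            )
        return label.label == "permanent_anoxia"

    probe = probe or default_probe
    lo, hi = bracket
    if probe(lo):
        raise ValueError(f"bracket low end R_tilde={lo} is already permanent; widen the search")
    if not probe(hi):
        raise ValueError(f"bracket high end R_tilde={hi} is not permanent; widen the search")
    return _bisect(probe, lo, hi, tol)


def fit_boundary_linear(points) -> float:
    """Origin-constrained slope a of R_dagger = a * kt (i.e. a / kt_inv).

    ``points`` are (kt_inv, R_tilde_dagger) pairs with kt_inv > 1
    (influx not saturation-limited).  Least squares through the origin in
    the variable x = 1/kt_inv.
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("need at least 2 boundary points")
    x = np.array([1.0 / k for k, _ in pts])
    y = np.array([r for _, r in pts])
    return float(np.dot(x, y) / np.dot(x, x))


def fit_boundary_saturating(points, p0=(18.9, 4.1, 1.9)) -> BoundaryFit:
    """Fit R_dagger = A/(B + C*kt_inv) to boundary points.

    The form is degenerate under joint rescaling of (A, B, C); the
    identifiable quantities are the ratios A/B (the small-kt_inv plateau)
    and A/C (the large-kt_inv slope in kt), reported alongside the raw
    coefficients.
    """
    from scipy.optimize import curve_fit

    pts = list(points)
    if len(pts) < 4:
        raise ValueError("need at least 4 boundary points")
    k = np.array([p[0] for p in pts])
    r = np.array([p[1] for p in pts])
    if not (k.min() < 1.0 < k.max()):
        warnings.warn("boundary points should span kt_inv < 1 and > 1 for a stable fit")

    def f(kinv, A, B, C):
        return A / (B + C * kinv)

    coef, _ = curve_fit(f, k, r, p0=p0, maxfev=20000)
    A, B, C = (float(c) for c in coef)
    resid = r - f(k, A, B, C)
    return BoundaryFit(
        form="saturating",
        coefficients={"A": A, "B": B, "C": C, "A_over_B": A / B, "A_over_C": A / C},
        residuals=resid,
        points=pts,
    )


def annulus_scaling(
    ccell_0_list,
    base: PhysicalParams,
    config: SolverConfig = SolverConfig(N=512),
    kt_inv: float = 0.7,
    t_max_factor: float = 1.0,
):
    """Initial annulus width versus cell concentration, and the implied uptake rate.

    For each concentration the dimensional preset is nondimensionalized
    (``kt`` adjusted so the reduced influx ratio stays at ``kt_inv``), the
    model is integrated through core formation, and ``ell_init`` (annulus
    width at maximal core extent) is restored to micrometers.  The
    penetration-length law ell_init = sqrt(DO2*cO2_sat/(kO2*ccell_0)) is
    then fitted for the single parameter kO2 (closed-form least squares),
    and the log-log slope of ell_init vs ccell_0 is reported.

    Returns (DataFrame, fit dict with keys kO2, loglog_slope).
    """
    import pandas as pd

    rows = []
    for c0 in ccell_0_list:
        l_O2 = math.sqrt(
            base.DO2 * base.cO2_sat * MOLECULES_PER_UM3_PER_UM / (base.kO2_0 * c0)
        )
        kt = base.DO2 / (kt_inv * l_O2) if kt_inv > 0 else base.DO2  # placeholder for Dirichlet
        p = base.with_(ccell_0=c0, kt=kt)
        dp = nondimensionalize(p)
        grid = build_grid(dp.R_tilde, config.N)
        t_max = t_max_factor * max(30.0, 0.6 * dp.R_tilde**2)
        traj = simulate(dp, grid, t_max=t_max, cadence=0.25, dt_max=config.dt_max)
        trace = core_trace(traj)
        if not trace.formed:
            warnings.warn(f"ccell_0={c0}: no anoxic core formed; excluded from the fit")
            continue
        rows.append(
            {
                "ccell_0": c0,
                "R_tilde": dp.R_tilde,
                "l_O2_um": dp.l_O2,
                "ell_init_tilde": trace.ell_init,
                "ell_init_um": trace.ell_init * dp.l_O2,
            }
        )
    if len(rows) < 3:
        raise ValueError("need at least 3 concentrations that form a core")
    df = pd.DataFrame(rows)
    # ell = sqrt(A/c) with A = DO2*cO2_sat/kO2: linear LS in sqrt(A)
    ell = df["ell_init_um"].to_numpy()
    c = df["ccell_0"].to_numpy()
    sqrtA = np.sum(ell / np.sqrt(c)) / np.sum(1.0 / c)
    kO2 = base.DO2 * base.cO2_sat * MOLECULES_PER_UM3_PER_UM / sqrtA**2
    slope = float(np.polyfit(np.log(c), np.log(ell), 1)[0])
    return df, {"kO2": float(kO2), "loglog_slope": slope}
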