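"""Physical parameters, constitutive laws, and nondimensionalization.

The model describes a quasi-2D droplet of radius ``R`` (gap height much
smaller than ``R``) containing an initially uniform suspension of swimming
aerobic bacteria at concentration ``ccell_0``.  Oxygen enters only through
the air-liquid interface at the droplet rim (a Robin / mass-transfer
condition with coefficient ``kt``), diffuses inward, and is consumed by the
cells through Michaelis-Menten kinetics with half-saturation ``K``.  Cells
move by active diffusion (``Dcell_0``) and aerotaxis: a drift up the
gradient of the receptor-occupancy function ``f(c) = c/(K_chi + c)`` with
aerotactic coefficient ``chi_0``.  When oxygen falls below the critical
concentration ``c_crit`` the cells lose motility; both motility parameters
and the per-cell uptake rate are switched off smoothly by a tanh of width
``delta``.

Everything downstream works in dimensionless variables: lengths are scaled
by the oxygen penetration length ``l_O2 = sqrt(DO2*cO2_sat/(kO2_0*ccell_0))``,
times by ``tau = l_O2**2/DO2``, oxygen by ``cO2_sat`` and cells by
``ccell_0``.  This leaves two control parameters, the reduced droplet radius
``R_tilde = R/l_O2`` and the reduced mass-transfer coefficient
``kt_tilde = kt*l_O2/DO2`` (its inverse compares diffusive transport to
interfacial influx), plus the fixed constitutive ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

__all__ = [
    "MOLECULES_PER_UM3_PER_UM",
    "PhysicalParams",
    "DimensionlessParams",
    "motility_switch",
    "oxygen_sensing",
    "uptake_rate",
    "penetration_length",
    "nondimensionalize",
    "redimensionalize",
    "peclet",
    "load_preset",
    "available_presets",
]

#: 1 μM expressed in molecules per μm³ (Avogadro's number / 1e21).
MOLECULES_PER_UM3_PER_UM = 602.214


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional model constants.

    Units: diffusivities in μm²/s, concentrations in μM, per-cell uptake in
    molecules s⁻¹ cell⁻¹, cell concentration in cells/μm³, lengths in μm,
    ``kt`` in μm/s, ``henry_H`` in μM/mmHg.
    """

    DO2: float
    cO2_sat: float
    K: float
    K_chi: float
    kO2_0: float
    Dcell_0: float
    chi_0: float
    c_crit: float
    delta: float
    kt: float
    R: float
    ccell_0: float
    henry_H: float = 250.0 / 160.0

    def __post_init__(self) -> None:
        positive = {
            "DO2": self.DO2,
            "cO2_sat": self.cO2_sat,
            "K": self.K,
            "K_chi": self.K_chi,
            "kO2_0": self.kO2_0,
            "c_crit": self.c_crit,
            "delta": self.delta,
            "kt": self.kt,
            "R": self.R,
            "ccell_0": self.ccell_0,
            "henry_H": self.henry_H,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.Dcell_0 < 0 or self.chi_0 < 0:
            raise ValueError("Dcell_0 and chi_0 must be non-negative")
        # motility loss must occur far below the sensing scale, c_crit << K_chi
        if not self.c_crit < self.K_chi / 5:
            raise ValueError(
                f"c_crit={self.c_crit} must be well below K_chi={self.K_chi} "
                "(require c_crit < K_chi/5)"
            )
        if not self.delta < self.c_crit:
            raise ValueError("switch width delta must be smaller than c_crit")

    def with_(self, **kwargs) -> "PhysicalParams":
        """Copy with selected fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DimensionlessParams:
    """The reduced parameter set actually integrated.

    ``l_O2`` (μm) and ``tau`` (s) are carried only for unit restoration and
    may be NaN when a run is specified purely in dimensionless form.
    """

    R_tilde: float
    kt_tilde: float
    Dcell_tilde: float
    chi_tilde: float
    K_tilde: float
    K_chi_tilde: float
    c_crit_tilde: float
    delta_tilde: float
    l_O2: float = math.nan
    tau: float = math.nan

    def __post_init__(self) -> None:
        if not self.R_tilde > 0:
            raise ValueError("R_tilde must be positive")
        for name in ("K_tilde", "K_chi_tilde", "c_crit_tilde", "delta_tilde"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        if self.kt_tilde <= 0:
            raise ValueError("kt_tilde must be positive (use math.inf for a perfect interface)")

    @property
    def kt_inv(self) -> float:
        """DO2/(kt*l_O2): diffusion-to-influx rate ratio. 0 for a perfect interface."""
        return 0.0 if math.isinf(self.kt_tilde) else 1.0 / self.kt_tilde

    @classmethod
    def from_ratios(
        cls,
        R_tilde: float,
        kt_inv: float,
        *,
        Dcell_tilde: float = 0.025,
        chi_tilde: float = 0.3,
        K_tilde: float = 1.0 / 250.0,
        K_chi_tilde: float = 7.0 / 250.0,
        c_crit_tilde: float = 0.3 / 250.0,
        delta_tilde: float = 0.1 / 250.0,
        l_O2: float = math.nan,
        tau: float = math.nan,
    ) -> "DimensionlessParams":
        """Build a run specification directly in dimensionless form.

        Defaults are the ratios implied by the default dimensional constants
        (DO2 = 2e3 μm²/s, cO2_sat = 250 μM, K = 1 μM, K_chi = 7 μM,
        Dcell_0 = 50 μm²/s, chi_0 = 600 μm²/s, c_crit = 0.3 μM,
        delta = 0.1 μM).  ``kt_inv = 0`` means a perfectly absorbing
        interface (Dirichlet limit).
        """
        if kt_inv < 0:
            raise ValueError("kt_inv must be non-negative")
        kt_tilde = math.inf if kt_inv == 0 else 1.0 / kt_inv
        return cls(
            R_tilde=R_tilde,
            kt_tilde=kt_tilde,
            Dcell_tilde=Dcell_tilde,
            chi_tilde=chi_tilde,
            K_tilde=K_tilde,
            K_chi_tilde=K_chi_tilde,
            c_crit_tilde=c_crit_tilde,
            delta_tilde=delta_tilde,
            l_O2=l_O2,
            tau=tau,
        )

    def with_(self, **kwargs) -> "DimensionlessParams":
        return replace(self, **kwargs)


def motility_switch(cO2, X0, c_crit, delta):
    """Smooth on/off factor for motility and uptake at low oxygen.

    Returns ``X0/2 * (1 + tanh((cO2 - c_crit)/delta))``: approximately
    ``X0`` well above ``c_crit``, approximately 0 well below.  Applies
    identically to the active diffusivity, the aerotactic coefficient and
    the per-cell uptake rate.
    """
    if not delta > 0:
        raise ValueError("switch width delta must be positive")
    return 0.5 * X0 * (1.0 + np.tanh((np.asarray(cO2, dtype=float) - c_crit) / delta))


def oxygen_sensing(cO2, K_chi):
    """Receptor-occupancy sensing function f(c) = c/(K_chi + c) in [0, 1)."""
    c = np.asarray(cO2, dtype=float)
    if np.any(c < 0):
        raise ValueError("cO2 must be non-negative")
    if not K_chi > 0:
        raise ValueError("K_chi must be positive")
    return c / (K_chi + c)


def uptake_rate(cO2, ccell, params: PhysicalParams):
    """Volumetric oxygen uptake in μM/s.

    Michaelis-Menten consumption with the per-cell maximal rate switched off
    below ``c_crit``; the molecules s⁻¹ μm⁻³ result is converted to μM/s.
    """
    c = np.asarray(cO2, dtype=float)
    n = np.asarray(ccell, dtype=float)
    if np.any(c < 0) or np.any(n < 0):
        raise ValueError("cO2 and ccell must be non-negative")
    k = motility_switch(c, params.kO2_0, params.c_crit, params.delta)
    return k * n * c / (params.K + c) / MOLECULES_PER_UM3_PER_UM


def penetration_length(params: PhysicalParams) -> float:
    """Oxygen penetration length l_O2 = sqrt(DO2*cO2_sat/(kO2_0*ccell_0)) in μm.

    The depth over which boundary-supplied oxygen diffuses before being
    consumed by the population at its maximal rate; it sets the motile
    annulus width at core formation and scales as ``ccell_0**-0.5``.
    """
    if not (params.kO2_0 > 0 and params.ccell_0 > 0):
        raise ValueError("kO2_0 and ccell_0 must be positive")
    c_sat_molec = params.cO2_sat * MOLECULES_PER_UM3_PER_UM
    return math.sqrt(params.DO2 * c_sat_molec / (params.kO2_0 * params.ccell_0))


def nondimensionalize(params: PhysicalParams) -> DimensionlessParams:
    """Reduce a dimensional parameter set to the dimensionless one.

    Lengths scale by ``l_O2``, times by ``tau = l_O2**2/DO2``, oxygen by
    ``cO2_sat``, cells by ``ccell_0``.  With this scaling the uptake term
    has unit prefactor by construction of ``l_O2``.
    """
    l = penetration_length(params)
    tau = l * l / params.DO2
    return DimensionlessParams(
        R_tilde=params.R / l,
        kt_tilde=params.kt * l / params.DO2,
        Dcell_tilde=params.Dcell_0 / params.DO2,
        chi_tilde=params.chi_0 / params.DO2,
        K_tilde=params.K / params.cO2_sat,
        K_chi_tilde=params.K_chi / params.cO2_sat,
        c_crit_tilde=params.c_crit / params.cO2_sat,
        delta_tilde=params.delta / params.cO2_sat,
        l_O2=l,
        tau=tau,
    )


def redimensionalize(
    dp: DimensionlessParams,
    cO2_sat: float,
    ccell_0: float,
    henry_H: float | None = None,
) -> PhysicalParams:
    """Rebuild dimensional quantities from (DimensionlessParams, cO2_sat, ccell_0).

    Inverse of :func:`nondimensionalize` up to floating-point roundoff;
    requires finite ``l_O2`` and ``tau``.
    """
    if not (math.isfinite(dp.l_O2) and math.isfinite(dp.tau)):
        raise ValueError("l_O2 and tau must be finite to restore units")
    DO2 = dp.l_O2**2 / dp.tau
    c_sat_molec = cO2_sat * MOLECULES_PER_UM3_PER_UM
    return PhysicalParams(
        DO2=DO2,
        cO2_sat=cO2_sat,
        K=dp.K_tilde * cO2_sat,
        K_chi=dp.K_chi_tilde * cO2_sat,
        kO2_0=DO2 * c_sat_molec / (dp.l_O2**2 * ccell_0),
        Dcell_0=dp.Dcell_tilde * DO2,
        chi_0=dp.chi_tilde * DO2,
        c_crit=dp.c_crit_tilde * cO2_sat,
        delta=dp.delta_tilde * cO2_sat,
        kt=dp.kt_tilde * DO2 / dp.l_O2,
        R=dp.R_tilde * dp.l_O2,
        ccell_0=ccell_0,
        henry_H=cO2_sat / 160.0 if henry_H is None else henry_H,
    )


def peclet(vc: float, L: float, DO2: float) -> float:
    """Péclet number vc*L/DO2 for evaporation-driven convection."""
    if not DO2 > 0:
        raise ValueError("DO2 must be positive")
    if vc < 0 or L < 0:
        raise ValueError("vc and L must be non-negative")
    return vc * L / DO2


# ---------------------------------------------------------------------------
# Presets: flat key = value text files, one parameter per line.

def available_presets() -> list[str]:
    files = resources.files("oxydrop").joinpath("presets")
    return sorted(p.name[: -len(".txt")] for p in files.iterdir() if p.name.endswith(".txt"))


def load_preset(name: str) -> PhysicalParams:
    """Load a named dimensional parameter preset (e.g. ``"bmb-minimal"``)."""
    path = resources.files("oxydrop").joinpath("presets").joinpath(f"{name}.txt")
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown preset {name!r}; available: {available_presets()}") from None
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, raw = line.partition("=")
        values[key.strip()] = float(raw)
    return PhysicalParams(**values)
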