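"""Shared fixtures: reference simulations cached once per session.

The three reference droplet conditions (small dilute, large concentrated,
small concentrated) are expensive enough that every test touching them
reuses one cached run.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oxydrop.model import DimensionlessParams
from oxydrop.solver import build_grid, simulate

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def transient_traj():
    """(2.7, 1) at N=256, run through core vanishing and past it."""
    p = DimensionlessParams.from_ratios(
        2.7, 1.0, l_O2=1400.0 / 2.7, tau=(1400.0 / 2.7) ** 2 / 2000.0
    )
    g = build_grid(2.7, 256)
    return simulate(p, g, t_max=260.0, cadence=0.5)


@pytest.fixture(scope="session")
def transient_traj_512():
    """(2.7, 1) at production resolution N=512, stopping at core vanishing."""
    p = DimensionlessParams.from_ratios(
        2.7, 1.0, l_O2=1400.0 / 2.7, tau=(1400.0 / 2.7) ** 2 / 2000.0
    )
    g = build_grid(2.7, 512)
    return simulate(p, g, t_max=30.0 * 2.7**2, cadence=0.5, stop_on_vanish=True)


@pytest.fixture(scope="session")
def permanent_traj():
    """(9.3, 0.7) at N=512 through the post-formation quiescent window."""
    p = DimensionlessParams.from_ratios(
        9.3, 0.7, l_O2=3400.0 / 9.3, tau=(3400.0 / 9.3) ** 2 / 2000.0
    )
    g = build_grid(9.3, 512)
    return simulate(p, g, t_max=450.0, cadence=0.5)


@pytest.fixture(scope="session")
def aerobic_traj():
    """(0.96, 2.8) at N=256 with a tight step cap for the early transient."""
    p = DimensionlessParams.from_ratios(0.96, 2.8)
    g = build_grid(0.96, 256)
    return simulate(p, g, t_max=100.0, cadence=0.5, dt_max=1e-3)
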