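#!/usr/bin/env python
"""Synthetic-imaging round trip: how well does the quantification pipeline
recover the known observables from noisy phantom micrographs?

Renders the small concentrated droplet trajectory into bright-field and
Ru(dpp) fluorescence stacks (5% multiplicative noise, m=3 shape
imperfection), runs the calibration-inversion / sector-averaging pipeline,
and compares recovered annulus width, core-vanishing time and annulus O2
content against the simulation ground truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from oxydrop.model import DimensionlessParams
from oxydrop.observables import core_radius_profile
from oxydrop.solver import build_grid, simulate
from oxydrop.synthetic import PhantomConfig, phantom_droplet, recover_observables

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

SEED = 11
R_UM, CCELL, CSAT = 1400.0, 0.04, 250.0

p = DimensionlessParams.from_ratios(2.7, 1.0, l_O2=R_UM / 2.7, tau=(R_UM / 2.7) ** 2 / 2000.0)
g = build_grid(2.7, 256)
traj = simulate(p, g, t_max=260.0, cadence=0.5)

frames = slice(0, traj.n_states, 8)
r_um = g.centers * p.l_O2
cc = traj.c_cell[frames] * CCELL
co = traj.c_oxy[frames] * CSAT
times_s = traj.times[frames] * p.tau

cfg = PhantomConfig(R_um=R_UM, pixel_size_um=10.0, eps_boundary=0.03, mode=3,
                    noise=0.05, seed=SEED)
ph = phantom_droplet(r_um, cc, co, times_s, cfg)
rec = recover_observables(ph, c_crit_uM=0.3)

r_truth = np.array([core_radius_profile(c, r_um, R_UM, 0.3) for c in co])


def vanish(rc, ts):
    formed = np.nonzero(rc > 0)[0]
    gone = np.nonzero(rc[formed[0]:] == 0)[0]
    return ts[formed[0] + gone[0]]


ell_init_truth = R_UM - r_truth.max()
tv_truth, tv_rec = vanish(r_truth, times_s), vanish(rec["r_core_um"], times_s)
o2_truth = np.array(
    [np.sum(co[k][r_um >= r_truth[k]] * r_um[r_um >= r_truth[k]])
     / (CSAT * np.sum(r_um[r_um >= r_truth[k]])) for k in range(len(co))]
)
post = np.nonzero(r_truth > 0)[0][0]

report = pd.DataFrame(
    [
        {"observable": "ell_init (μm)", "truth": ell_init_truth,
         "recovered": rec["ell_init_um"],
         "rel_error": abs(rec["ell_init_um"] - ell_init_truth) / ell_init_truth},
        {"observable": "t_vanish (min)", "truth": tv_truth / 60, "recovered": tv_rec / 60,
         "rel_error": abs(tv_rec - tv_truth) / tv_truth},
        {"observable": "annulus O2 (max abs err, post-formation)", "truth": float("nan"),
         "recovered": float("nan"),
         "rel_error": float(np.max(np.abs(rec["total_o2"][post:] - o2_truth[post:])))},
    ]
)
report.to_csv(OUT / "phantom_recovery.csv", index=False)
pd.DataFrame({"t_s": times_s, "r_core_truth_um": r_truth,
              "r_core_recovered_um": rec["r_core_um"],
              "total_o2_truth": o2_truth, "total_o2_recovered": rec["total_o2"]}
             ).to_csv(OUT / "phantom_core_trace.csv", index=False)

print(f"phantom: {cc.shape[0]} frames, {ph['brightfield'].shape[1:]} px, "
      f"5% noise, eps=0.03 m=3, seed={SEED}")
print(report.to_string(index=False))
print(f"Wrote {OUT/'phantom_recovery.csv'} and phantom_core_trace.csv")
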