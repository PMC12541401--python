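#!/usr/bin/env python
"""Morphological state diagram in (R_tilde, kt_inv) and its boundaries.

Sweeps a grid of droplet conditions, classifies each as aerobic /
transient / permanent, bisects the onset and permanence boundaries, and
fits the two boundary forms: the origin-constrained line R = a*kt and the
saturating form R = A/(B + C*kt_inv).  Writes the sweep table, boundary
points and fit coefficients under results/, plus a diagram figure.
"""

import json
from pathlib import Path

from oxydrop.state_diagram import (
    SolverConfig,
    fit_boundary_linear,
    fit_boundary_saturating,
    onset_boundary,
    permanence_boundary,
    sweep,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

R_GRID = [0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 12.0, 20.0]
KT_INV_GRID = [0.1, 0.3, 1.0, 2.0, 4.0]

config = SolverConfig(N=192, horizon_cap=1500.0)
res = sweep(R_GRID, KT_INV_GRID, config)
df = res.to_frame()
df.to_csv(OUT / "state_diagram_sweep.csv", index=False)
print(df.pivot(index="R_tilde", columns="kt_inv", values="label").to_string())
print(f"\nlabel ordering along R_tilde monotone at every kt_inv: {res.monotone_ok}")

# --- boundaries ---------------------------------------------------------
onset_points = []
for kt_inv in (0.3, 0.7, 1.0, 2.0):
    r_star, _ = onset_boundary(kt_inv, config, bracket=(0.3, 2.5), tol=0.1)
    onset_points.append((kt_inv, r_star))
    print(f"onset boundary  kt_inv={kt_inv}: R_tilde* = {r_star:.2f}")

perm_brackets = {0.3: (1.5, 6.0), 0.5: (1.5, 5.0), 1.0: (1.0, 4.0), 2.0: (1.0, 3.0), 4.0: (0.7, 2.0)}
perm_points = []
for kt_inv, bracket in perm_brackets.items():
    r_dag, _ = permanence_boundary(kt_inv, config, bracket=bracket, tol=0.25)
    perm_points.append((kt_inv, r_dag))
    print(f"permanence boundary  kt_inv={kt_inv}: R_tilde+ = {r_dag:.2f}")

a = fit_boundary_linear([p for p in perm_points if p[0] > 1])
sat = fit_boundary_saturating(perm_points)
fits = {
    "linear_prefactor_a": a,
    "saturating": sat.coefficients,
    "onset_points": onset_points,
    "permanence_points": perm_points,
}
(OUT / "boundary_fits.json").write_text(json.dumps(fits, indent=2) + "\n")
print(f"\nlinear boundary fit (kt_inv > 1): R_tilde = {a:.2f} * kt_tilde")
print(f"saturating fit ratios: plateau A/B = {sat.coefficients['A_over_B']:.2f}, "
      f"slope A/C = {sat.coefficients['A_over_C']:.2f}")

# --- figure -------------------------------------------------------------
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

colors = {"aerobic": "tab:orange", "transient_anoxia": "tab:gray", "permanent_anoxia": "tab:blue"}
fig, ax = plt.subplots(figsize=(5, 4))
for lab, c in colors.items():
    part = df[df.label == lab]
    ax.scatter(1.0 / part.kt_inv, part.R_tilde, c=c, label=lab.replace("_", " "), s=40)
kk = np.geomspace(0.2, 12, 100)
ax.plot(kk, np.ones_like(kk), "-", color="tab:orange", lw=1, label=r"$\tilde R = 1$")
ax.plot(kk, a * kk, "--", color="tab:blue", lw=1, label=rf"$\tilde R = {a:.1f}\,\tilde k_t$")
A, B, C = (sat.coefficients[k] for k in "ABC")
ax.plot(kk, A / (B + C / kk), "-", color="tab:blue", lw=1)
for kt_inv, r in perm_points:
    ax.plot(1.0 / kt_inv, r, "k+", ms=10)
ax.set_xscale("log")
ax.set_yscale("log")
ax.set_xlabel(r"$\tilde k_t$")
ax.set_ylabel(r"$\tilde R$")
ax.legend(fontsize=7)
fig.tight_layout()
fig.savefig(OUT / "state_diagram.png", dpi=150)
print(f"Wrote sweep, fits and {OUT/'state_diagram.png'}")
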