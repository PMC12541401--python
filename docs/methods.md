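# Methods

## The model

`oxydrop` simulates an initially uniform suspension of swimming aerobic
bacteria (concentration `ccell,0`) confined to a quasi-2D liquid droplet of
radius `R` between two gas-impermeable plates, so dissolved oxygen enters
only at the air–liquid interface at the rim. Because the gap height
(130 μm) is far smaller than `R` and the measured Péclet number of
residual evaporation-driven flow is ≪ 1, all fields are treated as
depth-integrated and axisymmetric: two coupled reaction–diffusion
equations for oxygen `cO2(r,t)` and cells `ccell(r,t)` on the disc.

Oxygen diffuses (diffusivity `DO2`) and is consumed by Michaelis–Menten
kinetics with half-saturation `K`, at a maximal per-cell rate `kO2,0`.
Cells perform run-and-tumble motility, coarse-grained into an active
diffusivity `Dcell,0` plus an aerotactic drift `χ ∇f(cO2)` up the gradient
of the receptor-occupancy function `f(c) = c/(Kχ + c)` (first-order
receptor binding, dissociation constant `Kχ`). Below a critical oxygen
concentration `ccrit ≪ Kχ` cells lose motility; the active diffusivity,
the aerotactic coefficient and the uptake rate are all multiplied by the
same smooth switch `s(c) = (1 + tanh((c − ccrit)/δ))/2`. Boundary
conditions: Robin mass-transfer influx
`DO2 ∂r cO2 = kt (cO2,sat − cO2)` at `r = R`, zero total cell flux at both
boundaries, symmetry at the center. Cells neither grow nor lyse: total
cell count is a conserved quantity.

Scaling lengths by the oxygen penetration length
`l_O2 = sqrt(DO2 · cO2,sat / (kO2,0 · ccell,0))`, times by
`τ = l_O2²/DO2`, oxygen by `cO2,sat` and cells by `ccell,0` gives the
uptake term unit prefactor and leaves two control parameters — the reduced
radius `R̃ = R/l_O2` and the reduced influx ratio `k̃t⁻¹ = DO2/(kt l_O2)` —
plus the constitutive ratios `D̃cell`, `χ̃`, `K̃`, `K̃χ`, `c̃crit`, `δ̃`.

Note on `l_O2`: dimensional analysis forces the square root in the
definition above; the linear combination `DO2·cO2,sat/(kO2·ccell,0)` is an
area. With the defaults below, `l_O2 ≈ 307 μm` at 8×10¹⁰ cells/mL in
minimal-media conditions, matching the observed ~300 μm annulus scale.

## Parameters and defaults

| parameter | default | units | role / rationale |
|---|---|---|---|
| `DO2` | 2×10³ | μm²/s | O2 diffusivity in water at 30 °C |
| `cO2_sat` | 250 | μM | air-saturated concentration (≈160 mmHg via Henry's law) |
| `K` | 1 | μM | Michaelis constant of respiration |
| `K_chi` | 7 | μM | aerotactic sensing dissociation constant |
| `kO2_0` | 4×10⁴ (minimal) / 3×10⁵ (rich) | molecules s⁻¹ cell⁻¹ | maximal per-cell uptake |
| `Dcell_0` | 50 | μm²/s | active diffusivity in buffer |
| `chi_0` | 600 | μm²/s | aerotactic coefficient (drift ~2 μm/s across the annulus) |
| `c_crit` | 0.3 | μM | motility-loss threshold, well below `K_chi` |
| `delta` | 0.1 | μM | switch width (sharp but nonzero) |
| `kt` | 9.31 | μm/s | interfacial mass transfer (`k̃t⁻¹ ≈ 0.7` at `l_O2` = 307 μm) |

`K`, `K_chi` and the two `kO2_0` values are measured quantities; the
remaining constants are provisional, chosen once from typical literature
ranges for *E. coli*, and are config-overridable (presets `bmb-minimal`,
`lb-rich`, `peo-4x`; the last models a semidilute-polymer medium as a
fourfold increase of both motility coefficients). Dimensionless runs use
the ratios implied by these defaults: `D̃cell = 0.025`, `χ̃ = 0.3`,
`K̃ = 4×10⁻³`, `K̃χ = 0.028`, `c̃crit = 1.2×10⁻³`, `δ̃ = 4×10⁻⁴`.

Unit conventions: concentrations in μM internally, cells in cells/μm³,
1 μM = 602.214 molecules/μm³. When a run is specified directly by
`(R̃, k̃t⁻¹)`, dimensional restoration uses `l_O2 = R/R̃` and
`τ = l_O2²/DO2`, which avoids any dependence on the provisional constants.

## Numerical scheme

Cell-centered finite volumes on a uniform radial grid (`N = 512` control
volumes by default; faces at `j·h`, `h = R̃/N`). The `1/r` geometry enters
only through face areas, so nothing is evaluated at `r = 0` and the
symmetry condition is automatic. Per time step:

1. The tanh switch and the sensing function are evaluated at cell centers
   and faces; the aerotactic face velocity is `v = χ̃ s ∂r f`. The step is
   `dt = min(dt_max, 0.4·h/max|v|)` with `dt_max = 5×10⁻³`.
2. Cells: explicit first-order upwind advection (conservative face
   fluxes; positivity is guaranteed at CFL ≤ 0.4 because
   `r_{i−1/2} + r_{i+1/2} = 2 r_i`), then backward-Euler diffusion with
   face coefficient `D̃cell·s` (tridiagonal solve). Should positivity
   still fail, the step is rejected and retried at half `dt`.
3. Oxygen: backward-Euler diffusion with the Robin condition folded into
   an effective boundary conductance `k_eff = 1/(k̃t⁻¹ + h/2)` (exact for
   the two-point flux; `k̃t⁻¹ = 0` reduces to a second-order Dirichlet
   limit), then the Michaelis–Menten sink applied as a positivity-
   preserving semi-implicit (Patankar) update
   `c ← c / (1 + dt·s·c̃cell/(K̃ + c))`.

The Patankar treatment is what makes production runs affordable: near
anoxia the uptake relaxation rate is `~c̃cell/K̃ ≈ 10³` in dimensionless
units, and a fully explicit reaction step would force `dt ~ 10⁻⁴` and
~10⁷ steps per run. Both implicit operators are M-matrices, so oxygen
obeys the maximum principle `0 ≤ c̃O2 ≤ 1` and cells stay non-negative;
the advective and diffusive cell fluxes telescope, so total cell content
is conserved to roundoff (measured drift < 10⁻¹⁰ per run, reported in the
trajectory's mass ledger). Verification: a uniform no-uptake state is a
fixed point; Robin relaxation toward saturation is monotone; the
steady constant-sink disc problem matches the closed form
`c = c_edge − Q(R̃² − r̃²)/4` to 10⁻⁴; an independent explicit-Euler
integration of the same semi-discrete system matches the production
solver to 3×10⁻⁴ relative L2 at `t̃ = 1`.

The switch width `δ̃ = 4×10⁻⁴` maps to a sub-grid radial band
(~4×10⁻³ l_O2 at typical gradients), so the scheme sees an effectively
step-like switch; the finite-volume formulation is robust to this, and
resolution is judged by grid convergence of the observables instead: the
formation-phase annulus width changes by 0.03% from `N = 512` to 1024.
The interface position during the later slow creep converges only first
order (~2–5% per grid doubling), as expected for a front advected by
upwind fluxes.

## Observables

* **Anoxic-core radius** `r_core`: the outer edge of the contiguous
  central region with `c̃O2 < c̃crit` (the same threshold as the motility
  switch, since the core is defined by both anoxia and motility loss);
  the crossing is located by linear interpolation between cell centers.
* **Annulus width** `ℓ = R̃ − r_core`. `ℓ_init` is measured at maximal
  core extent — the core overshoots during formation and is then partly
  eroded, so the maximum is the unambiguous reference point.
* **Plateau width**: the interface recedes in ever-rarer grid-cell hops;
  the plateau is declared at the earliest post-formation time from which
  `r_core` moves by at most one grid spacing over one droplet-scale
  diffusion time `R̃²`, and `ℓ` is averaged over that window. (In the
  large concentrated reference condition the core never becomes exactly
  stationary: it creeps on `t̃ ~ 10³–10⁴` scales as cells continue to
  accumulate; the plateau definition captures the experimentally relevant
  quasi-stationary value.)
* **Total annulus O2 content**: `∫ c̃O2 r̃ dr̃` over `[r_core, R̃]`,
  normalized by the same integral of the saturated state.
* **Classification**: *aerobic* if oxygen never drops below `c̃crit`
  anywhere (tracked per step, not per output frame); *transient anoxia*
  if a core forms and vanishes; *permanent anoxia* if a core persists
  when the run is steady (max field rate < 10⁻⁶ sustained over one time
  unit) or has reached the classification horizon
  `t_max = max(100, 30·R̃²)`. The horizon multiple is calibrated to the
  measured erosion timescale of the transient reference condition
  (`t_vanish ≈ 19.5·R̃²` at `(R̃, k̃t⁻¹) = (2.7, 1)`); runs stopped before
  the horizon without vanishing or steadiness are *indeterminate*,
  signalling that `t_max` must be raised.

## State diagram and fits

The `(R̃, k̃t⁻¹)` plane is swept by full classification runs; at every
`k̃t⁻¹` the labels must order aerobic → transient → permanent along `R̃`
(asserted on every sweep). Two boundaries are bisected: the onset of
anoxia (bracket tolerance 0.1 in `R̃`, probes stop at first anoxia) and
the transient/permanent boundary (tolerance 0.25, probes stop at
vanishing or steadiness; near the boundary the vanishing time diverges,
so a finite horizon biases the boundary slightly downward — an accepted
cost at this tolerance). Two forms are fitted to the permanence boundary:
the origin-constrained line `R̃ = a·k̃t` on points with `k̃t⁻¹ > 1`
(closed-form least squares), and the saturating form
`R̃ = A/(B + C·k̃t⁻¹)` (Levenberg–Marquardt seeded at (18.9, 4.1, 1.9)).
The saturating form is degenerate under joint rescaling of (A, B, C), so
the identifiable ratios `A/B` (small-`k̃t⁻¹` plateau) and `A/C`
(large-`k̃t⁻¹` slope) are reported alongside the raw coefficients.

The annulus-width scaling analysis re-runs the full model at several cell
concentrations (dimensional minimal-media preset, `kt` adjusted to hold
`k̃t⁻¹ = 0.7`), extracts `ℓ_init`, restores micrometers through each run's
own `l_O2`, and fits `ℓ_init = sqrt(DO2·cO2,sat/(kO2·ccell,0))` for the
single parameter `kO2` (closed-form least squares in `sqrt`-space), also
reporting the log–log slope (−0.54 measured vs −0.5 for the pure law; the
mild steepening is the disc-curvature effect on `ℓ̃_init`, which drifts
from 1.20 at `R̃ = 3.9` to 1.12 at `R̃ = 11`).

## Synthetic observables

The `synthetic` module emulates what the experiments actually record, so
the quantification pipeline can be tested end-to-end with exact ground
truth:

* **Bright-field**: Beer–Lambert attenuation `I/I₀ = exp(−ε·ccell·path)`
  of the depth-integrated cell column (`path` = 130 μm gap). The
  attenuation coefficient is auto-calibrated so the densest column
  transmits ~20% and is recorded in the phantom metadata.
* **O2 fluorescence**: a Ru(dpp) probe quenched by oxygen,
  `Ifluo = 1 + 6.5·exp(−pO2/3)` (pO2 in mmHg), with Henry's law
  `cO2 = H·pO2` anchored so 160 mmHg ↦ `cO2,sat`. The probe carries
  essentially no information above ~60 mmHg — near-saturated regions
  recover only a lower bound — and its exponential calibration is
  strongly convex.
* **Phantoms**: radial profiles are rendered onto a pixel grid with a
  droplet-shape imperfection `R(θ) = R(1 + ε cos mθ)` (the pattern
  follows the distorted boundary by radial rescaling) and multiplicative
  Gaussian pixel noise; generation is bit-reproducible given the recorded
  seed.
* **Recovery** follows the experimental order: raw intensities are
  averaged within a narrow angular sector into radial bins first, and the
  calibrations are inverted on the averaged profiles. Inverting per pixel
  before averaging would bias recovered `cO2` by tens of μM under 5%
  noise because of the calibration's convexity. Inner bins whose sector
  holds fewer than 20 pixels fall back to full-circle averaging (the
  shape imperfection scales with `r` and is negligible there); a 3-bin
  radial median suppresses residual single-bin noise before the core
  threshold is located, and a 5-frame temporal median stabilizes the
  event times, while `ℓ_init` is read from the unsmoothed series so the
  fast formation peak is not clipped.

Measured recovery accuracy on 5%-noise phantoms of the small concentrated
droplet trajectory (ε = 0.03, m = 3, across 5 seeds): `ℓ_init` within
5.7%, vanishing time within 13.2%, annulus O2 content within 1.1%
(absolute) after formation. What the phantoms do *not* emulate: optical
point-spread and depth sectioning, photobleaching, shot-noise statistics
(the multiplicative Gaussian is a proxy), the bright interfacial cell
band's scattering, and absolute calibration constants — so passing
recovery tests demonstrate self-consistency of the quantification chain,
not absolute calibration against real microscopes.

## Where the defaults land, and known limitations

With the provisional constants the model reproduces the full
phenomenology: the three morphological regimes in their expected regions
of the `(R̃, k̃t⁻¹)` plane with monotone ordering, core formation within
1–2 diffusive times, square-root annulus scaling with concentration
(recovered `kO2 = 2.9×10⁴` vs the generating 4×10⁴), a permanence
boundary `∝ k̃t` (prefactor 3.4) that saturates at small `k̃t⁻¹`, and
machine-precision cell conservation.

Several quantitative observables are first-order sensitive to the
motility coefficients, whose true values for these experiments are not
published in the sources available here. With `χ̃/D̃cell = 12` the
aerotactic drift strips the annulus into a dense rim layer, which (i)
lets oxygen penetrate deeper, widening the quasi-stationary annulus to
~1.5·l_O2 (≈550–590 μm) instead of the observed ~300 μm; (ii) slows core
erosion — the transient reference condition vanishes at `t̃ ≈ 142`
(≈320 min) rather than ~70 min, because erosion is paced by a ~0.2%
imbalance between rim influx and total uptake; (iii) moves the anoxia
onset at `k̃t⁻¹ = 0.7` to `R̃* ≈ 1.7` rather than ≈1, and lets the small
dilute reference droplet dip briefly to 0.63·`ccrit` at its center (a
grid- and step-converged result), so the strict classifier calls it
transient rather than aerobic; and (iv) inverts the expected ordering of
the fourfold-enhanced-motility scenario: the 4× rim layer consumes
incoming oxygen as a screen and the core persists, whereas a 2× variant
erodes faster than baseline as expected. The annulus O2 content
normalized by the annulus' own saturation value *decreases* during
erosion here (the annulus expands into barely-aerated territory faster
than it reaerates) and rises only after the core vanishes. The
corresponding end-to-end tests assert the published values and are
expected to fail under these defaults; all constants are overridable, so
measured values can be substituted without code changes.

Further limitations: no hydrodynamics or collective swirls, no
viscoelastic coupling beyond the effective 4× motility scenario, no
z-resolved sedimentation (the immotile core's settling is subsumed into
the depth-integrated description), no growth, lysis or adaptation, and a
boundary that neither moves nor deforms.
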