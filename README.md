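# oxydrop

Reaction–diffusion modeling of oxygen-driven self-organization in
confined bacterial droplets.

When a suspension of swimming aerobic bacteria (*E. coli*) is confined to
a quasi-2D droplet that receives oxygen only at its rim, the population
can spontaneously separate into a concentrated **anoxic core of immotile
cells** surrounded by a **motile, oxygenated annulus** — permanently in
large droplets, transiently in smaller ones, or not at all in small
dilute ones. `oxydrop` implements the continuum model of this feedback
loop (cells consume oxygen; oxygen gradients switch motility and steer
aerotaxis; the redistributed cells reshape the gradients), the
observable-extraction pipeline used to quantify it, and the analyses that
map the three regimes onto a two-parameter state diagram. It is aimed at
quantitative microbial-ecology and active-matter researchers who want a
fast, tested implementation of the model and its analysis chain.

## Model

Depth-integrated, axisymmetric fields cO2(r,t) and ccell(r,t) on a disc
of radius R:

    ∂cO2/∂t   = DO2 ∇²cO2 − s(cO2) kO2,0 ccell cO2/(K + cO2)
    ∂ccell/∂t = ∇·[ s(cO2) Dcell,0 ∇ccell − s(cO2) χ0 ccell ∇f(cO2) ]

with aerotactic sensing f(c) = c/(Kχ + c), the motility/uptake switch
s(c) = ½(1 + tanh[(c − ccrit)/δ]), Robin influx
DO2 ∂r cO2|R = kt (cO2,sat − cO2) at the rim, zero total cell flux at
both boundaries, and uniform saturated initial conditions. Scaling by the
oxygen penetration length l_O2 = √(DO2 cO2,sat / (kO2,0 ccell,0)) and
τ = l_O2²/DO2 reduces the system to two control parameters:

* **R̃ = R/l_O2** — droplet size relative to how far boundary oxygen
  penetrates before being consumed;
* **k̃t⁻¹ = DO2/(kt l_O2)** — diffusive transport relative to
  interfacial influx.

The solver is a conservative finite-volume scheme (implicit diffusion,
upwinded aerotactic advection, positivity-preserving semi-implicit
uptake), compiled with numba; a production run takes seconds. See
`docs/methods.md` for the numerics, observable definitions, and an honest
account of which published numbers the default constants do and do not
reproduce.

## Worked example

```python
from oxydrop import DimensionlessParams, build_grid, simulate, core_trace, classify_regime

params = DimensionlessParams.from_ratios(R_tilde=2.7, kt_inv=1.0)
grid = build_grid(2.7, 512)
traj = simulate(params, grid, t_max=220.0, cadence=0.5)
trace = core_trace(traj)
print(classify_regime(traj, horizon=220.0).label)   # transient_anoxia
print(round(trace.t_form, 2), round(trace.t_vanish, 1))  # 1.1 141.7
```

An anoxic core forms at t̃ ≈ 1.1 (≈2.5 min for a 1.4 mm droplet) and is
eroded away by t̃ ≈ 142 as aerotactic accumulation at the rim reshapes
the oxygen field. The numbered drivers under `analysis/` run the full
studies and write tables under `results/`. For example:

```text
$ python analysis/01_reference_regimes.py
small_dilute (R~=0.96, kt^-1=2.8): transient_anoxia; core forms at t~=1.69
  vanishes at t~=4.8 (85 min)
  annulus width at max core extent: 0.657 l_O2; total cells drift 1.9e-12 (of 2.9)
large_concentrated (R~=9.3, kt^-1=0.7): permanent_anoxia; core forms at t~=1.05
  annulus width at max core extent: 1.127 l_O2; total cells drift 3.9e-12 (of 271.7)
small_concentrated (R~=2.7, kt^-1=1.0): transient_anoxia; core forms at t~=1.1
  vanishes at t~=141.7 (318 min)
  annulus width at max core extent: 1.082 l_O2; total cells drift 4.3e-12 (of 22.9)
```

i.e. the large concentrated droplet keeps its core permanently with a
motile annulus of ≈1.1 l_O2 (≈410 μm) at formation, the small
concentrated one loses its core, and the small dilute one stays
functionally aerobic apart from a brief, marginal dip below the motility
threshold at its center. `analysis/02_annulus_scaling.py` recovers the
per-cell uptake rate from the √(1/ccell,0) annulus-width law
(2.9×10⁴ vs the generating 4×10⁴ molecules s⁻¹ cell⁻¹),
`analysis/03_state_diagram.py` maps the three-regime diagram and fits its
two boundaries, and `analysis/04_phantom_recovery.py` validates the
imaging-quantification chain on noisy synthetic micrographs (annulus
width recovered to 3%, core-vanishing time to 3%, annulus O2 content to
1% at 5% pixel noise).

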