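# Minimal motility buffer (BMB): non-growing swimming cells, large concentrated droplet.
# One parameter per line, key = value.  Units noted per key.
DO2 = 2.0e3          # oxygen diffusivity, μm²/s
cO2_sat = 250.0      # air-saturated oxygen concentration, μM
K = 1.0              # Michaelis constant for uptake, μM
K_chi = 7.0          # aerotactic sensing dissociation constant, μM
kO2_0 = 4.0e4        # maximal per-cell uptake, molecules s⁻¹ cell⁻¹ (minimal media)
Dcell_0 = 50.0       # active cell diffusivity, μm²/s
chi_0 = 600.0        # aerotactic coefficient, μm²/s
c_crit = 0.3         # motility-loss threshold, μM
delta = 0.1          # switch sharpness, μM
kt = 9.3142          # interfacial mass-transfer coefficient, μm/s (kt_inv ≈ 0.7 at this l_O2)
R = 3.4e3            # droplet radius, μm
ccell_0 = 0.08       # initial cell concentration, cells/μm³ (8e10 cells/mL)
henry_H = 1.5625     # Henry's-law conversion, μM/mmHg (160 mmHg ↦ cO2_sat)
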