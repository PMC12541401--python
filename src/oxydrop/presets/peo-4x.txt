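# Semidilute 5 MDa PEO scenario: cell swimming enhanced ~4x relative to buffer,
# modeled as a fourfold increase of both the active diffusivity and the
# aerotactic coefficient.  Small concentrated droplet.
DO2 = 2.0e3          # μm²/s
cO2_sat = 250.0      # μM
K = 1.0              # μM
K_chi = 7.0          # μM
kO2_0 = 4.0e4        # molecules s⁻¹ cell⁻¹
Dcell_0 = 200.0      # μm²/s (4x buffer)
chi_0 = 2400.0       # μm²/s (4x buffer)
c_crit = 0.3         # μM
delta = 0.1          # μM
kt = 9.3142          # μm/s
R = 1.4e3            # μm
ccell_0 = 0.04       # cells/μm³ (4e10 cells/mL)
henry_H = 1.5625     # μM/mmHg
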