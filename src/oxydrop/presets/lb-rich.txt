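# Nutrient-rich media (LB): active metabolism raises the per-cell uptake rate.
DO2 = 2.0e3          # μm²/s
cO2_sat = 250.0      # μM
K = 1.0              # μM
K_chi = 7.0          # μM
kO2_0 = 3.0e5        # molecules s⁻¹ cell⁻¹ (nutrient-rich media)
Dcell_0 = 50.0       # μm²/s
chi_0 = 600.0        # μm²/s
c_crit = 0.3         # μM
delta = 0.1          # μM
kt = 9.3142          # μm/s
R = 3.4e3            # μm
ccell_0 = 0.08       # cells/μm³
henry_H = 1.5625     # μM/mmHg
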