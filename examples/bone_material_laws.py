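"""Evaluate the density-dependent bone material laws across the physiological range.

Builds a small table of apparent density vs. elastic modulus, yield stress and
softening parameters, exactly as the FE pipeline assigns them per element.
"""

import numpy as np

from symphysim import materials as M

print("rho_CT -> apparent density rho = 1.54 rho_CT + 0.0784 (g/cm^3)")
for rho_ct in (0.1, 0.25, 0.6, 1.1):
    print(f"  rho_CT = {rho_ct:5.2f}  ->  rho = {M.density_from_ct(rho_ct):6.3f}")

print("\nrho      tissue       E [MPa]   sigma_y [MPa]  sigma_min  eps_ab")
for rho in (0.3, 0.5, 0.7, 0.945, 1.2, 1.6, 1.9):
    tis = M.classify_tissue(rho)
    E = M.elastic_modulus(rho, tis)
    sy = M.yield_stress(rho)
    try:
        soft = M.softening_params(rho)
        extra = f"{soft.sigma_min:9.2f} {soft.eps_ab:8.3f}"
    except M.DegenerateMaterialError:
        extra = "   (softening undefined)"
    print(f"{rho:5.3f}  {tis.value:11s} {E:9.1f} {sy:13.3f} {extra}")

# The two yield branches intersect near the compact/cancellous threshold:
gap = M.yield_stress(0.945 + 1e-9) - M.yield_stress(0.945 - 1e-9)
print(f"\nYield-branch gap at rho = 0.945: {gap:.4f} MPa (continuous to < 0.1 MPa)")

# Full uniaxial curve at the threshold density (elastic rise, plateau,
# softening to the residual stress):
c = M.bone_curve(0.945)
print("\nStress-strain breakpoints at rho = 0.945 (strain, stress MPa):")
for eps, sig in c.breakpoints:
    print(f"  ({eps:8.5f}, {sig:7.3f})")
print(
    "The curve is linear to the yield point, perfectly plastic to the softening\n"
    "onset, degrades with the printed negative slope, then holds the residual stress."
)
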