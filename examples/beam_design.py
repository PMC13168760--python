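"""Pillar mechanics: stiffness, force conversion, and the design sweep.

Computes the lateral spring constant of the standard elliptical pillar,
round-trips the material modulus, and sweeps the height/thickness design
space under the 38 uN per-pillar reference load.
"""

from pillarforce import (
    PillarGeometry,
    back_calculate_modulus,
    deflection_under_load,
    design_space_sweep,
    force_from_deflection,
    lateral_stiffness,
    shear_modulus,
)

geom = PillarGeometry()  # a=300 um, b=200 um, h=4 mm, E=2.414 MPa, nu=0.49
k = lateral_stiffness(geom)
print(f"formula spring constant k = {k:.4f} uN/um (3EI/h^3)")
print(f"shear modulus mu = {shear_modulus(2.414, 0.49):.3f} MPa")
print(f"modulus back-calculated from k: {back_calculate_modulus(k, geom):.3f} MPa")

# a mechanically calibrated spring constant can replace the formula value
k_cal = 0.249
delta = 100.0  # um of pillar-tip deflection read off the video
print(f"F = k*delta = {force_from_deflection(k_cal, delta):.1f} uN "
      f"at delta = {delta:.0f} um (calibrated k = {k_cal} uN/um)")

print(f"deflection under the 38 uN reference load: "
      f"{deflection_under_load(geom, 38.0):.0f} um")

sweep = design_space_sweep(
    heights_mm=[3.0, 3.5, 4.0, 4.5, 5.0],
    semi_minor_axes_um=[150.0, 200.0, 250.0, 300.0],
)
print("\ndesign sweep (taller/thinner pillars deflect more under 38 uN):")
print(sweep.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
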