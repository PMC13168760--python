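"""Fiber alignment: orientation histograms and the orientation index.

OI = sum_i P(theta_i) cos(theta_i): 1 for fibers parallel to the
interpillar axis, 0 for perpendicular fibers, 2/pi (~0.637) when isotropic.
"""

import numpy as np

from pillarforce import OrientationDistribution, oi_pipeline
from pillarforce.orientation import orientation_index
from pillarforce.synthetic import generate_fiber_image, stripe_image

print("idealized limits:")
print(f"  all mass at   0 deg -> OI = {orientation_index(OrientationDistribution.point_mass(0.0)):.3f}")
print(f"  all mass at  90 deg -> OI = {orientation_index(OrientationDistribution.point_mass(90.0)):.3f}")
print(f"  uniform 36 bins     -> OI = {orientation_index(OrientationDistribution.uniform()):.3f} (2/pi = {2/np.pi:.3f})")

print("\nfrom images (Fourier directionality + OI):")
for angle in (0.0, 45.0, 90.0):
    oi = oi_pipeline(stripe_image(angle))
    print(f"  stripes at {angle:+5.1f} deg -> OI = {oi:.3f}")

image, truth = generate_fiber_image(modal_angle_deg=10.0, concentration=8.0, snr=8.0, seed=0)
print(f"  von Mises texture (mode {truth.fiber_modal_angle_deg} deg, kappa "
      f"{truth.fiber_concentration}) -> OI = {oi_pipeline(image):.3f}")
iso, _ = generate_fiber_image(modal_angle_deg=None, concentration=0.0, seed=0)
print(f"  isotropic texture -> OI = {oi_pipeline(iso):.3f} (expect ~0.637)")
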