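"""Orientation tuning of the combined operator and its parameter dependence.

Builds the combined operator (anisotropic Laplacian of an elongated
Gaussian receptive field), sweeps a thin bar through 180 degrees of
orientation, and extracts the tuning-curve FWHM.  Then it shows the two
headline parameter dependences: strong sharpening with receptive-field
elongation, near-insensitivity to the Laplacian weight ratio b^2/a^2.
"""

import numpy as np

import v1maps as v
from v1maps.tuning import fwhm, orientation_tuning, sweep_fwhm

al = v.ALParams.from_ratio(1.0)          # b^2 = a^2 (isotropic Laplacian)
rf = v.RFParams.from_aspect(2.0)         # sigma_x = 0.18 mm, sigma_x/sigma_y = 2

curve = orientation_tuning(135.0, al, rf)
print(f"default operator (aspect 2, b2=a2): FWHM = {fwhm(curve):.2f} deg "
      f"(experimental membrane-potential width: ~45 deg)")

aspects = [1.5, 2.0, 2.5, 4.0, 6.5]
m = sweep_fwhm([1.0], aspects)
print("FWHM vs RF elongation sigma_x/sigma_y:")
for a, f in zip(aspects, m[0]):
    print(f"  aspect {a:>3}: {f:6.2f} deg")

ratios = [1.0, 5.0, 100.0]
m2 = sweep_fwhm(ratios, [2.5], phi0=45.0)[:, 0]
print("FWHM vs Laplacian weight ratio b2/a2 at aspect 2.5:")
for r, f in zip(ratios, m2):
    print(f"  b2/a2 {r:>5}: {f:6.2f} deg")
print(f"drop from b2/a2=1 to 5: {m2[0] - m2[1]:.2f} deg "
      f"(tuning is set by the RF envelope, not the Laplacian anisotropy)")
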