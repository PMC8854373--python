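"""Spatially pooled measurements near and far from a pinwheel centre.

Optical-imaging pixels and extracellular electrodes pool the activity of
all neurons within tens of micrometres.  This script averages model
responses under a 40-um Gaussian site weight at (i) an iso-orientation
domain and (ii) a pinwheel centre, then traces tuning width and response
strength along a path leaving the centre, for both the Gaussian and the
zero-mean Mexican-hat pooling profile.
"""

import numpy as np

import v1maps as v
from v1maps.pooling import averaged_tuning_curve, distance_profile
from v1maps.tuning import fwhm

lat = v.tile_lattice(3, 3)
al = v.ALParams.from_ratio(1.0)
rf = v.RFParams.from_aspect(2.0)

site = v.find_iso_orientation_site(lat)
f_iso = fwhm(averaged_tuning_curve(site, lat, al, rf))
f_ctr = fwhm(averaged_tuning_curve((0.5, 0.5), lat, al, rf))
print(f"iso-orientation site {tuple(round(s, 3) for s in site)} "
      f"(local OP {lat.op.angle_at(*site):.1f} deg): pooled FWHM = {f_iso:.1f} deg")
print(f"pinwheel centre (0.5, 0.5): pooled FWHM = {f_ctr:.1f} deg "
      f"({f_ctr / f_iso:.2f}x broader; single neurons there stay sharp)")

d = np.arange(0.0, 0.201, 0.02)
for kind in ("gaussian", "mexican_hat"):
    prof = distance_profile((0.5, 0.5), (-1.0, -1.0), d, lat, al, rf, kind=kind)
    print(f"\n{kind} pooling, distance from centre (um) / HWHM (deg) / strength (a.u.):")
    for dist, h, s in zip(prof.distances, prof.hwhm, prof.strength):
        print(f"  {1000 * dist:5.0f}  {h:6.2f}  {s:8.4f}")

# Gaussian pooling: width falls and strength rises monotonically with
# distance.  Mexican-hat pooling adds the overshoot in strength (and a
# shallow dip in width) seen in pinwheel-distance measurements.
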