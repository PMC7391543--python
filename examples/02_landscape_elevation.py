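"""Derive the elevation landscape implied by an OCN.

The slope-area relationship s ~ A^(gamma-1) fixes every channel slope given
the slope at the outlet (here 0.01); walking upstream and accumulating the
per-link drops yields elevations.  Larger drainage areas mean gentler
slopes, so the relief concentrates in the headwaters.
"""

import numpy as np

import ocnlab as o
from ocnlab.annealing import AnnealingSchedule

lat = o.build_lattice(20, 20, cellsize=500.0, outlets=(("S", 3),))
state = o.anneal(o.initial_flow(lat), schedule=AnnealingSchedule(seed=1))

slopes = o.assign_slopes(state, slope0=0.01)
elev = o.compute_elevation(state, slopes, z0=0.0)

print(f"slopes: outlet {slopes[lat.outlets[0]]:.4f}, "
      f"steepest headwater {slopes.max():.4f}")
print(f"elevation: 0 m at the outlet up to {np.nanmax(elev.z):.1f} m at the divide")
print(f"mean elevation: {np.nanmean(elev.z):.1f} m")

o.write_asc("scratch_elevation.asc", elev.z, lat)
print("elevation raster written to scratch_elevation.asc (ESRI ASCII grid)")
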