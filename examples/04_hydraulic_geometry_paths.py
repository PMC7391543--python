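"""Leopold hydraulic geometry and along-network distances.

Width, depth and velocity follow downstream power laws of drainage area
(exponents 0.5 / 0.4 / 0.1, summing to 1 by continuity); with a 5 m wide
outlet the headwater channels come out decimeters wide.  Network distances
between nodes sum the flow paths down to the lowest common junction.
"""

import numpy as np

import ocnlab as o
from ocnlab.annealing import AnnealingSchedule
from ocnlab.geometry import HydraulicParams

lat = o.build_lattice(20, 20, cellsize=500.0, outlets=(("S", 3),))
state = o.anneal(o.initial_flow(lat), schedule=AnnealingSchedule(seed=1))
rn = o.extract_rn(state, 5)

params = HydraulicParams(width_max=5.0, depth_max=0.6, velocity_max=1.0)
hg = o.hydraulic_geometry(rn, params)
outlet = int(np.nonzero(rn.receiver < 0)[0][0])
print(f"outlet: width {hg['width'][outlet]:.1f} m, "
      f"depth {hg['depth'][outlet]:.2f} m, velocity {hg['velocity'][outlet]:.2f} m/s")
head = int(np.argmin(rn.A))
print(f"smallest channel (A = {rn.A[head]} px): width {hg['width'][head]:.2f} m, "
      f"depth {hg['depth'][head]:.2f} m")

dto, D = o.path_lengths(rn)
far = int(np.argmax(dto))
print(f"\nlongest flow path to the outlet: {dto[far] / 1000:.1f} km")
finite = D[np.isfinite(D) & (D > 0)]
print(f"mean pairwise network distance: {finite.mean() / 1000:.1f} km")
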