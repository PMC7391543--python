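"""Invasion dynamics of a riverine species on an OCN.

One individual is seeded at the headwater farthest from the outlet of the
worked-example network; local growth is Beverton-Holt (r = 1.05, K = 10
individuals per meter of channel width) and 10% of each local population
disperses per step.  Comparing unbiased movement (p_d = 0.5) with a
downstream preference (p_d = 0.7) shows the classical trade-off: faster
downstream colonization, slower establishment upstream, and a slightly
smaller metapopulation at equilibrium.
"""

import numpy as np

import ocnlab as o
from ocnlab.annealing import AnnealingSchedule
from ocnlab.geometry import HydraulicParams
from ocnlab.metapop import MetapopParams, run

lat = o.build_lattice(20, 20, cellsize=500.0, outlets=(("S", 3),))
state = o.anneal(o.initial_flow(lat), schedule=AnnealingSchedule(seed=1))
rn = o.extract_rn(state, 5)
widths = o.hydraulic_geometry(rn, HydraulicParams(width_max=5.0))["width"]

outlet = int(np.nonzero(rn.receiver < 0)[0][0])
trajs = {}
for p_d in (0.5, 0.7):
    params = MetapopParams.from_widths(widths, kappa=10.0, r=1.05, g=0.1, p_d=p_d)
    trajs[p_d] = run(rn, params, t_max=800)

print(f"network: {rn.n_nodes} RN nodes, onset node {trajs[0.5].onset_node} "
      f"(farthest headwater)")
for p_d, traj in trajs.items():
    print(f"\np_d = {p_d}:")
    print(f"  total population at t=100: {traj.totals[99]:.1f}")
    print(f"  outlet reaches equilibrium at t = {traj.equilibrium_time(outlet)}")
    print(f"  total at equilibrium (t=800): {traj.totals[-1]:.1f}")
print("\nDownstream bias colonizes the outlet sooner but ends up with the"
      "\nsmaller metapopulation, because upstream nodes fill more slowly.")
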