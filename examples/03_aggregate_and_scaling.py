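"""Aggregate an OCN and measure its river scaling laws.

A drainage-area threshold selects the channelized portion of the lattice
(RN level); contracting chains between sources, confluences and the outlet
gives the AG level used in metapopulation experiments.  The drainage-area
exceedance exponent beta and Hack's-law exponent h are the classical
fingerprints of real rivers (beta ~= 0.43, h ~= 0.57); they only emerge in
the scaling regime, so this example uses a 100 x 100 lattice (fits on very
small lattices are dominated by finite-size curvature).
"""

import ocnlab as o
from ocnlab.annealing import AnnealingSchedule

lat = o.build_lattice(100, 100, outlets=(("S", 50),))
state = o.anneal(o.initial_flow(lat), schedule=AnnealingSchedule(seed=1))

rn = o.extract_rn(state, 20)
ag = o.extract_ag(rn)
print(f"FD level: {lat.n_pixels} nodes (every pixel)")
print(f"RN level (A_T = 20 px): {rn.n_nodes} nodes")
print(f"AG level: {ag.n_nodes} nodes, max Strahler order "
      f"{int(ag.stream_order.max())}")
print(f"drainage density: {o.drainage_density(rn):.3f} inverse planar units")

scan = o.area_threshold_scan(state, [1, 5, 20, 50, 200])
print("\nthreshold scan (A_T, N_AG, max order):")
for _, row in scan.iterrows():
    print(f"  {row.A_T:4.0f}  {row.nNodesAG:5.0f}  {row.maxStrahler:.0f}")

beta = -o.exceedance_exponent(state.areas, lat.n_pixels).exponent
h = o.hack_exponent(state, rn).exponent
print(f"\nexceedance exponent beta = {beta:.3f} (real rivers ~0.43)")
print(f"Hack exponent h = {h:.3f} (real rivers ~0.57)")
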