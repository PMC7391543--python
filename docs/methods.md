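# Methods

## Model

An optimal channel network (OCN) is a spanning forest on a regular lattice
of `N = dimX · dimY` pixels. Every non-outlet pixel drains to exactly one
of its 8 Moore neighbors; outlet pixels (declared on the perimeter) drain
nowhere and root the forest. Drainage area `A_i` counts the pixels whose
downstream walk passes through `i` (itself included) and satisfies
`(I − Wᵀ)A = 1`, with `W` the sparse downstream adjacency matrix. The
energy of a configuration is

    H = Σ_i A_i^γ,   γ ∈ (0, 1], default 0.5.

Link lengths are omitted from `H`: they are constant up to the √2 diagonal
factor, which does not change the minimizers. Because every spanning tree
is a local minimum of `H` with respect to single rewires that preserve
treeness, the search is restricted to spanning forests with no loss.

### Annealing

One iteration proposes rewiring a uniformly random non-outlet pixel to a
uniformly random neighbor other than its current receiver. Proposals that
would create a loop (the pixel lies on the proposed receiver's downstream
path) are rejected and consume an iteration, as do Metropolis-rejected
uphill moves. Downhill moves are always accepted; an uphill move by `ΔH`
is accepted with probability `exp(−ΔH/T)`.

`ΔH` is evaluated incrementally: only pixels on the old and new downstream
paths up to their junction change area (by `∓A_pixel`), so the update walks
those two paths, reading `A^γ` from a precomputed table of integer powers.
The maintained energy is compared against a from-scratch recomputation at
the end of every run (tolerance `1e−9·H`) and, in tests, at every recorded
checkpoint.

The temperature is held at `T0` for an optional fraction of the budget and
then decays exponentially, `T(k) = T0 · exp(−coolingRate · (k − k0)/N)`,
with `coolingRate = 1` by default. Defaults:

| parameter | default | meaning |
|---|---|---|
| `n_iter` | `40·N` | iteration budget (40 sweeps) |
| `T0` | energy of the initial state | melt-then-quench start |
| `cooling_rate` | 1 | e-folding of T per N iterations |
| `no_cooling_fraction` | 0 | constant-T0 phase |
| `gamma` | 0.5 | slope–area / energy exponent |

The `T0` default matters. Deterministic initial states (see below) are
*directed* networks, and quenching them with a low temperature (e.g. one
calibrated to ~50 % acceptance of typical uphill moves) leaves the
optimization stuck in the directed-network universality class — measured
exceedance exponent β ≈ 0.35 and Hack exponent h ≈ 0.67, the
Scheidegger values, instead of the river values β ≈ 0.43, h ≈ 0.57.
Starting at `T0 = H(initial)` keeps acceptance near one until `T` reaches
the scale of single-move increments (after roughly `ln(H0/ΔH_typ)·N`
iterations), which erases enough of the initial heritage to land in the
OCN scaling regime while still leaving more than half the budget for the
quench. With a deliberately fast schedule (large `cooling_rate`, small
`T0`) the run becomes a greedy descent and the final network retains the
heritage of its initial state — the feasible-optimality behavior, which
the test suite checks explicitly.

One seeded generator drives each run; identical seeds give bitwise
identical results. Parity with any other implementation's random sequence
is a non-goal.

### Initial states

Two deterministic styles are provided. `"I"`: each pixel flows straight
toward the side of its nearest outlet (Manhattan metric, lowest index on
ties), then along that side. `"V"`: each pixel flows diagonally toward its
nearest outlet until aligned, then straight, producing two flow diagonals
converging on the outlet. Both strictly decrease the Manhattan distance to
the assigned outlet at every step, so they are valid forests for any
outlet configuration, including multiple outlets and all-perimeter
outlets. Non-periodic boundary pixels have 5 neighbors (3 at corners);
periodic lattices wrap to 8 everywhere.

## Landscape

Channel slopes follow `s_i = slope0 · (A_i/A_outlet)^(γ−1)` with the
outlet pixel carrying `slope0` itself; elevations accumulate `s_i · L_i`
upstream of the outlet elevation `z0`, with `L_i = cellsize` on lateral
and `√2 · cellsize` on diagonal links. Strictly the slope–area relation
holds only for channelized pixels; by default it is applied everywhere as
a first approximation. An optional channel threshold caps hillslope-pixel
slopes at the value attained at the threshold area, making hillslope
profiles linear. The relation is also multiscaling in reality (the
variance of slope conditional on area scales too); only the mean relation
is modeled.

## Aggregation and measurement conventions

- RN level: pixels with `A ≥ A_T`. Area monotonicity guarantees receivers
  of non-outlet RN pixels are RN pixels.
- AG level: RN sources (in-degree 0), confluences (in-degree ≥ 2, triple
  junctions allowed on 8-neighbor lattices) and outlets. An AG edge spans
  the RN chain from its node to the next AG node downstream; its length
  sums the traversed pixel links.
- Channel length: every RN pixel contributes its outgoing-link length
  (√2·cellsize on diagonals); outlet pixels contribute one lateral
  cellsize, so the unit-cell straight-network drainage density is exactly
  `N_RN / N`. Drainage density divides total RN length by lattice area.
- Strahler order: leaves are 1; a junction takes the maximum incoming
  order, +1 if that maximum arrives more than once.
- Subcatchments: an AG node owns the RN pixels of its outgoing edge
  (itself included, the downstream node excluded) plus all hillslope
  pixels whose flow first becomes channelized there.

## Scaling fits

Exceedance `P(A ≥ a)` is computed over distinct areas (each distinct `a`
one point, equally weighted) and fitted by OLS on log10 axes over
`a ≤ 0.02·N`; the 2 % cutoff excludes the finite-size tail. Hack's law is
fitted over RN nodes with `L` the *mainstream length*: the longest
upstream flow path from the drainage divide, measured on the full
flow-direction tree and sampled at RN nodes. Measuring `L` only over
above-threshold pixels instead would zero out lengths near `A_T` and bias
the OLS slope toward 1; the divide-to-node definition is the standard one
and the RN restriction still sets the fitted range's lower end. A
channel-only dynamic program (`upstream_lengths`) is also provided.

With the defaults, three-replica ensembles of 200 × 200 single-outlet OCNs
aggregated at `A_T = 20` pixels give AG node counts, maximum Strahler
orders, drainage densities and exponents in the ranges reported for this
construction (≈1050 nodes, order ≈6, D_d ≈ 0.148, β ≈ 0.43–0.45,
h ≈ 0.60–0.61); `scripts/acceptance.py` recomputes them. The 200 × 200
size is the smallest at which the 2 % cutoff leaves a comfortable scaling
window; the construct is invariant under coarse graining, so larger
lattices change the estimates only through finite-size effects.

## Hydraulic geometry and paths

Width, depth and velocity follow `q_i = q_max · (A_i/A_outlet)^e_q` with
defaults `e_w = 0.5, e_d = 0.4, e_v = 0.1`; the width exponent is the
classical square-root law and the three exponents must sum to 1 so that
`w·d·v ∝ Q ∝ A` (continuity). Discharge itself is never materialized —
drainage area stands in for it throughout. Pairwise network distances sum
each node's distance down to the lowest common downstream node; nodes in
different catchments are at infinite distance. The pairwise matrix is
O(n²·path length) and intended for RN/AG-sized networks, not for FD levels
of large lattices.

## Metapopulation model

On the RN network, with `P_i` the expected population at node `i`:

    P_i(t+1) = r P_i / (1 + (r−1) P_i / K_i)
             + g [ p_d Σ_j w_ji P_j + p_u Y_i P_recv(i)
                   − (p_d D_i + p_u U_i) P_i ]

Beverton–Holt growth (default `r = 1.05`), mobility `g = 0.1`, downstream
preference `p_d` (upstream `p_u = 1 − p_d`), `D_i`/`U_i` indicating the
existence of a downstream/upstream connection, and `Y_i` splitting
upstream movers among sibling branches proportionally to drainage area
(sibling weights sum to 1). The update is synchronous, all right-hand-side
terms at time `t`. Movement redistributes but never creates or destroys
individuals; the test suite verifies the g-terms sum to zero to 1e−12
relative. Carrying capacities default to `K_i = 10 · width_i` with widths
from the hydraulic-geometry module (outlet width 5 m in the worked
example). Invasions seed one individual at the node with the greatest
along-network distance to its outlet (ties to the lowest index, a declared
convention); equilibrium times are read off as the first step reaching
99 % of the population at a reference time (default t = 800). Demographic
stochasticity, stage structure and multi-species interactions are out of
scope.

## What the generator does and does not emulate

The annealed lattices reproduce the *statistical* geometry of river
networks — the area distribution, length–area scaling, aggregation-level
structure and hydraulic-geometry gradients. They do not reproduce any
particular river's planform, meandering, floodplain width variation or
multiscaling slope variance, and the elevation field is a first
approximation suitable for ecological gradients rather than
geomorphological analysis. Passing tests therefore certify statistical
realism of the analogues, not fidelity to any specific catchment.

## Numerical notes and limitations

- Areas are exact integers; energies are float64 with an integer-power
  lookup table, and the incremental/full energy drift is bounded at
  1e−9·H per run.
- Degenerate inputs: lattices need ≥ 4 pixels; 1-wide chains are allowed
  (their unique spanning tree makes annealing a no-op); γ must lie in
  (0, 1]; thresholds in [1, N].
- OLS power-law fits need ≥ 3 positive points inside the cutoff; tiny
  lattices (e.g. 8 × 8 with the 2 % cutoff) legitimately fail rather than
  return meaningless exponents.
- ESRI ASCII rasters use the pixel-center, column-major convention
  documented in `lattice.py`; rows are written north to south.
- The CLI stores the full resolved schedule (including the derived `T0`
  and seed) in `ocn_meta.json`, so every artifact is replayable.
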