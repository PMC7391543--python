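"""Energy functional and simulated-annealing search over spanning trees.

An optimal channel network is a spanning forest of the lattice minimizing

    H = sum_i A_i ** gamma,   gamma in (0, 1]

where A_i is the drainage area of pixel i.  Minimization rewires one pixel's
receiver at a time to a random Moore neighbor; proposals that would create a
loop are discarded, downhill moves are always accepted, and uphill moves are
accepted with probability exp(-dH / T) under an exponentially decaying
temperature.  Because every spanning tree is a local minimum of H, restricting
the search to trees loses nothing; what the cooling schedule controls is how
far the final network departs from the heritage of its initial state
(feasible optimality).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .lattice import (
    AreaField,
    FlowField,
    accumulate_areas,
    downstream_path,
    neighbor_table,
    validate_tree,
)

__all__ = [
    "AnnealingSchedule",
    "OCNState",
    "energy",
    "temperature",
    "creates_loop",
    "delta_energy",
    "anneal",
]

DEFAULT_GAMMA = 0.5
#: default iteration budget as a multiple of the pixel count
ITER_PER_PIXEL = 40


def energy(areas: AreaField | np.ndarray, gamma: float = DEFAULT_GAMMA) -> float:
    """Total energy expenditure H = sum(A ** gamma).

    Link lengths do not enter: they are constant over the lattice up to the
    diagonal factor, which does not change the minimizers.
    """
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    A = areas.A if isinstance(areas, AreaField) else np.asarray(areas)
    return float(np.sum(np.asarray(A, dtype=float) ** gamma))


@dataclass(frozen=True)
class AnnealingSchedule:
    """Cooling schedule and iteration budget.

    ``n_iter`` defaults to 40 sweeps of the lattice (40 * N).  ``T0``
    defaults to the energy of the initial state, so the search opens with
    a melt phase in which nearly every legal rewiring is accepted; the
    network only freezes once T decays to the scale of single-move energy
    increments, which is what lets it escape the directed scaling regime
    of the deterministic initial states.  After an optional
    constant-temperature phase covering ``no_cooling_fraction`` of the
    budget, T decays as ``T0 * exp(-cooling_rate * (k - k0) / N)``.
    """

    n_iter: Optional[int] = None
    T0: Optional[float] = None
    cooling_rate: float = 1.0
    no_cooling_fraction: float = 0.0
    record_every: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_iter is not None and self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.T0 is not None and self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if self.cooling_rate <= 0:
            raise ValueError("cooling_rate must be positive")
        if not 0.0 <= self.no_cooling_fraction < 1.0:
            raise ValueError("no_cooling_fraction must lie in [0, 1)")


def temperature(k: int, schedule: AnnealingSchedule, n_pixels: int) -> float:
    """Temperature at iteration k for a fully resolved schedule."""
    if schedule.T0 is None or schedule.n_iter is None:
        raise ValueError("schedule must have explicit T0 and n_iter")
    if not 0 <= k < schedule.n_iter:
        raise ValueError("iteration index out of range")
    k0 = int(schedule.no_cooling_fraction * schedule.n_iter)
    if k < k0:
        return schedule.T0
    return schedule.T0 * math.exp(-schedule.cooling_rate * (k - k0) / n_pixels)


@dataclass
class OCNState:
    """Annealing artifact: flow field, areas, and the optimization trace."""

    flow: FlowField
    areas: AreaField
    gamma: float
    H: float
    schedule: AnnealingSchedule
    history: pd.DataFrame  # columns: iteration, H, T, n_accepted (cumulative)

    @property
    def lattice(self):
        return self.flow.lattice

    def energy_check(self) -> float:
        """Recompute H from scratch (consistency diagnostic)."""
        return energy(accumulate_areas(self.flow), self.gamma)


def creates_loop(flow: FlowField, pixel: int, new_receiver: int) -> bool:
    """Would rewiring ``pixel`` to ``new_receiver`` create a cycle?

    True iff ``pixel`` lies on the current downstream path of
    ``new_receiver``.  The no-op proposal (current receiver) is never a
    loop.
    """
    lat = flow.lattice
    pixel, new_receiver = int(pixel), int(new_receiver)
    if pixel in lat.outlets:
        raise ValueError("outlet pixels are never rewired")
    nbr, count, _ = neighbor_table(lat)
    if new_receiver not in nbr[pixel, : count[pixel]]:
        raise ValueError(f"{new_receiver} is not a neighbor of {pixel}")
    if new_receiver == flow.receiver[pixel]:
        return False
    return pixel in downstream_path(flow, new_receiver)


def delta_energy(
    state: OCNState, pixel: int, new_receiver: int
) -> float:
    """Energy change of a legal rewire, via the affected paths only.

    Only pixels on the old and new downstream paths up to their junction
    change area (by -A_pixel and +A_pixel respectively); everything
    downstream of the junction is unaffected.
    """
    flow, A, gamma = state.flow, state.areas.A, state.gamma
    if creates_loop(flow, pixel, new_receiver):
        raise ValueError("rewiring would create a loop")
    r_old = int(flow.receiver[pixel])
    if new_receiver == r_old:
        return 0.0
    old_path = downstream_path(flow, r_old) if r_old >= 0 else []
    new_path = downstream_path(flow, int(new_receiver))
    old_set = {pixel} | set(old_path)
    junction = None
    new_seg = []
    for p in new_path:
        if p in old_set:
            junction = p
            break
        new_seg.append(p)
    old_seg = []
    for p in old_path:
        if p == junction:
            break
        old_seg.append(p)
    dA = int(A[pixel])
    dH = 0.0
    for p in old_seg:
        dH += (A[p] - dA) ** gamma - A[p] ** gamma
    for p in new_seg:
        dH += (A[p] + dA) ** gamma - A[p] ** gamma
    return float(dH)


def anneal(
    flow: FlowField,
    gamma: float = DEFAULT_GAMMA,
    schedule: AnnealingSchedule | None = None,
    validate_checkpoints: bool = False,
) -> OCNState:
    """Minimize H by Metropolis rewiring under the cooling schedule.

    The move proposal picks a uniform non-outlet pixel, then a uniform
    neighbor other than its current receiver; structurally illegal
    (loop-creating) proposals consume an iteration.  The energy is
    maintained incrementally along the affected downstream paths.  With
    ``validate_checkpoints`` the spanning-forest invariant is re-verified
    at every recorded iteration (slow; for testing).
    """
    report = validate_tree(flow)
    if not report:
        raise ValueError(f"invalid flow field: {report.issues}")
    if not 0.0 < gamma <= 1.0:
        raise ValueError("gamma must lie in (0, 1]")
    schedule = schedule or AnnealingSchedule()
    lat = flow.lattice
    n = lat.n_pixels

    flow = flow.copy()
    areas = accumulate_areas(flow)
    H = energy(areas, gamma)

    n_iter = schedule.n_iter if schedule.n_iter is not None else ITER_PER_PIXEL * n
    T0 = schedule.T0 if schedule.T0 is not None else H
    record_every = schedule.record_every or max(1, n_iter // 256)
    resolved = dataclasses.replace(
        schedule, n_iter=n_iter, T0=T0, record_every=record_every
    )
    k0 = int(resolved.no_cooling_fraction * n_iter)

    nbr, count, _ = neighbor_table(lat)
    candidates = np.setdiff1d(
        np.arange(n, dtype=np.int64), np.array(lat.outlets, dtype=np.int64)
    )
    pow_tab = np.arange(n + 1, dtype=np.float64) ** gamma
    mark = np.zeros(n, dtype=np.int64)
    stamp = 0

    # the kernel RNG stream is seeded once and consumed across chunks
    _kernels.seed_rng(int(np.uint32(resolved.seed)))

    rec_iter, rec_H, rec_T, rec_acc = [0], [H], [temperature(0, resolved, n)], [0]
    n_accepted = 0
    A = areas.A
    recv = flow.receiver
    k = 0
    while k < n_iter:
        k_next = min(k + record_every, n_iter)
        H, acc, stamp = _kernels.run_chunk(
            recv, A, nbr, count, candidates, pow_tab, H,
            k, k_next, T0, resolved.cooling_rate, k0, n, mark, stamp,
        )
        n_accepted += acc
        k = k_next
        rec_iter.append(k)
        rec_H.append(H)
        rec_T.append(temperature(k - 1, resolved, n))
        rec_acc.append(n_accepted)
        if validate_checkpoints:
            rep = validate_tree(flow)
            if not rep:
                raise RuntimeError(f"tree invariant broken at k={k}: {rep.issues}")
            if not np.array_equal(A, accumulate_areas(flow).A):
                raise RuntimeError(f"area bookkeeping broken at k={k}")

    history = pd.DataFrame(
        {"iteration": rec_iter, "H": rec_H, "T": rec_T, "n_accepted": rec_acc}
    )
    state = OCNState(flow, AreaField(A), gamma, H, resolved, history)
    # incremental H must agree with a from-scratch recomputation
    H_full = state.energy_check()
    if abs(H - H_full) > 1e-9 * max(1.0, abs(H_full)):
        raise RuntimeError("incremental energy drifted from full recomputation")
    state.H = H_full
    return state
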