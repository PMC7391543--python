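"""Aggregation of an OCN into river-network (RN) and aggregated (AG) levels.

A drainage-area threshold A_T (pixels) selects the channelized pixels: the
RN level keeps every pixel with A >= A_T, inheriting the flow-direction
receivers (area monotonicity guarantees the receiver of an RN pixel is
itself RN).  The AG level contracts RN chains: its nodes are the RN sources
(in-degree 0), confluences (in-degree >= 2) and outlets, and its edges span
the intervening RN paths.  Subcatchments (SC) assign every lattice pixel to
the AG node-or-edge its flow first enters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .annealing import OCNState
from .lattice import LatticeSpec, link_lengths

__all__ = [
    "LevelNetwork",
    "SubcatchmentPartition",
    "extract_rn",
    "extract_ag",
    "subcatchments",
    "strahler",
    "drainage_density",
    "area_threshold_scan",
]


@dataclass
class LevelNetwork:
    """A river network at one aggregation level (RN or AG).

    Node arrays are aligned; ``receiver`` holds the within-level index of
    the downstream node (-1 at outlets) and ``L`` the length in meters of
    each node's outgoing link (one lateral cellsize at outlets).  ``to_fd``
    maps node indices back to lattice pixels; AG networks additionally
    carry ``to_rn``.
    """

    level: str                       # "RN" or "AG"
    lattice: LatticeSpec
    receiver: np.ndarray             # int64 (n,)
    A: np.ndarray                    # int64 (n,) drainage area, pixels
    X: np.ndarray                    # float (n,) meters
    Y: np.ndarray                    # float (n,) meters
    L: np.ndarray                    # float (n,) meters
    to_fd: np.ndarray                # int64 (n,) pixel index
    to_rn: Optional[np.ndarray] = None
    stream_order: Optional[np.ndarray] = None

    @property
    def n_nodes(self) -> int:
        return len(self.to_fd)

    @property
    def A_m2(self) -> np.ndarray:
        return self.A.astype(float) * self.lattice.cellsize**2

    @property
    def W(self) -> sp.csr_matrix:
        src = np.nonzero(self.receiver >= 0)[0]
        return sp.csr_matrix(
            (np.ones(len(src)), (src, self.receiver[src])),
            shape=(self.n_nodes, self.n_nodes),
            dtype=np.int8,
        )

    @property
    def outlet_nodes(self) -> np.ndarray:
        return np.nonzero(self.receiver < 0)[0]

    @property
    def indegree(self) -> np.ndarray:
        r = self.receiver
        return np.bincount(r[r >= 0], minlength=self.n_nodes)


@dataclass
class SubcatchmentPartition:
    """Per-pixel AG-node identifier (index into the AG node arrays)."""

    label: np.ndarray


def extract_rn(state: OCNState, A_T: float) -> LevelNetwork:
    """RN level: pixels with drainage area >= A_T, FD receivers inherited."""
    lat = state.lattice
    n = lat.n_pixels
    if not 1 <= A_T <= n:
        raise ValueError(f"A_T must lie in [1, {n}]")
    A = state.areas.A
    nodes = np.nonzero(A >= A_T)[0]
    fd_to_rn = np.full(n, -1, dtype=np.int64)
    fd_to_rn[nodes] = np.arange(len(nodes))
    recv_fd = state.flow.receiver[nodes]
    recv = np.where(recv_fd >= 0, fd_to_rn[recv_fd], -1)
    if np.any((recv_fd >= 0) & (recv < 0)):
        raise RuntimeError("RN receiver fell below the area threshold")
    X, Y = lat.coords(nodes)
    L = link_lengths(state.flow)[nodes]
    net = LevelNetwork(
        level="RN", lattice=lat, receiver=recv, A=A[nodes].copy(),
        X=X, Y=Y, L=L, to_fd=nodes,
    )
    net.stream_order = strahler(net)
    return net


def extract_ag(rn: LevelNetwork) -> LevelNetwork:
    """AG level: sources, confluences and outlets of the RN network.

    Each AG edge follows the RN chain from its upstream AG node to the
    next AG node downstream; the edge length is the sum of the traversed
    pixel-link lengths (the downstream AG node excluded).
    """
    if rn.n_nodes == 0:
        raise ValueError("empty RN network")
    indeg = rn.indegree
    is_ag = (indeg == 0) | (indeg >= 2) | (rn.receiver < 0)
    ag_nodes = np.nonzero(is_ag)[0]
    rn_to_ag = np.full(rn.n_nodes, -1, dtype=np.int64)
    rn_to_ag[ag_nodes] = np.arange(len(ag_nodes))
    n_ag = len(ag_nodes)
    recv = np.full(n_ag, -1, dtype=np.int64)
    L = np.zeros(n_ag, dtype=float)
    for a, r in enumerate(ag_nodes):
        p = int(r)
        length = 0.0
        while True:
            nxt = int(rn.receiver[p])
            length += rn.L[p]
            if nxt < 0:
                recv[a] = -1
                break
            if is_ag[nxt]:
                recv[a] = rn_to_ag[nxt]
                break
            p = nxt
        L[a] = length
    net = LevelNetwork(
        level="AG", lattice=rn.lattice, receiver=recv,
        A=rn.A[ag_nodes].copy(), X=rn.X[ag_nodes].copy(),
        Y=rn.Y[ag_nodes].copy(), L=L,
        to_fd=rn.to_fd[ag_nodes].copy(), to_rn=ag_nodes,
    )
    net.stream_order = strahler(net)
    return net


def strahler(level: LevelNetwork) -> np.ndarray:
    """Strahler stream order per node of a forest-structured level.

    Leaves take order 1; a node fed by several edges takes the maximum
    incoming order, incremented when that maximum is attained more than
    once (triple junctions are handled by the same rule).
    """
    n = level.n_nodes
    recv = level.receiver
    indeg = level.indegree.copy()
    order = np.zeros(n, dtype=np.int64)
    best = np.zeros(n, dtype=np.int64)       # max incoming order so far
    best_count = np.zeros(n, dtype=np.int64)
    stack = list(np.nonzero(indeg == 0)[0])
    for i in stack:
        order[i] = 1
    n_done = 0
    while stack:
        i = stack.pop()
        n_done += 1
        r = int(recv[i])
        if r < 0:
            continue
        if order[i] > best[r]:
            best[r] = order[i]
            best_count[r] = 1
        elif order[i] == best[r]:
            best_count[r] += 1
        indeg[r] -= 1
        if indeg[r] == 0:
            order[r] = best[r] + (1 if best_count[r] > 1 else 0)
            stack.append(r)
    if n_done != n:
        raise ValueError("level network is not a forest")
    return order


def subcatchments(state: OCNState, ag: LevelNetwork) -> SubcatchmentPartition:
    """Assign every lattice pixel to an AG node's subcatchment.

    An AG node owns the RN pixels of its outgoing edge (itself included,
    the downstream AG node excluded) and every hillslope pixel whose flow
    first becomes channelized on that node-or-edge.
    """
    lat = state.lattice
    n = lat.n_pixels
    label = np.full(n, -1, dtype=np.int64)
    # paint RN chains with the AG node that starts them
    if ag.to_rn is None:
        raise ValueError("AG network lacks the RN back-map")
    # reconstruct the RN pixel set from AG edges by walking the FD field
    recv_fd = state.flow.receiver
    is_ag_fd = np.zeros(n, dtype=bool)
    is_ag_fd[ag.to_fd] = True
    ag_of_fd = np.full(n, -1, dtype=np.int64)
    ag_of_fd[ag.to_fd] = np.arange(ag.n_nodes)
    for a in range(ag.n_nodes):
        p = int(ag.to_fd[a])
        label[p] = a
        p = int(recv_fd[p])
        while p >= 0 and not is_ag_fd[p]:
            label[p] = a
            p = int(recv_fd[p])
    # hillslope pixels inherit the label of their receiver, downstream first
    from .landscape import _downstream_order

    for i in _downstream_order(state.flow):
        if label[i] < 0:
            r = int(recv_fd[i])
            label[i] = label[r] if r >= 0 else -1
    if np.any(label < 0):
        raise RuntimeError("subcatchment labeling left unassigned pixels")
    return SubcatchmentPartition(label)


def drainage_density(rn: LevelNetwork, lattice: LatticeSpec | None = None) -> float:
    """Total RN channel length per unit lattice area (1/m, or inverse
    planar units when cellsize is 1).

    With unit cells and diagonal-length differences neglected this reduces
    to N_RN / N.
    """
    lattice = lattice or rn.lattice
    area = lattice.n_pixels * lattice.cellsize**2
    return float(np.sum(rn.L)) / area


def area_threshold_scan(
    state: OCNState, thresholds: Sequence[float]
) -> pd.DataFrame:
    """Aggregate at each threshold and tabulate network descriptors.

    Returns one row per threshold with the normalized threshold a_T =
    A_T/N, the RN and AG node counts, the maximum Strahler order and the
    drainage density.
    """
    n = state.lattice.n_pixels
    rows = []
    for A_T in thresholds:
        if not 1 <= A_T <= n:
            raise ValueError(f"threshold {A_T} outside [1, {n}]")
        rn = extract_rn(state, A_T)
        ag = extract_ag(rn)
        rows.append(
            {
                "A_T": A_T,
                "a_T": A_T / n,
                "nNodesRN": rn.n_nodes,
                "nNodesAG": ag.n_nodes,
                "maxStrahler": int(ag.stream_order.max()),
                "drainageDensity": drainage_density(rn),
            }
        )
    return pd.DataFrame(rows)
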