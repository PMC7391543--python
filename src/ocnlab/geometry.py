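"""Downstream hydraulic geometry and network path lengths.

Leopold's downstream relations give channel width, depth and velocity as
power laws of discharge, which scales linearly with drainage area for
landscape-forming flows.  Each quantity therefore follows
``q_i = q_max * (A_i / A_outlet)**exp_q``, with the three exponents summing
to one by continuity (Q = w * d * v).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import LevelNetwork

__all__ = ["HydraulicParams", "hydraulic_geometry", "path_lengths"]


@dataclass(frozen=True)
class HydraulicParams:
    """Outlet values and downstream exponents of the Leopold relations.

    Width goes as the square root of drainage area; the depth and velocity
    exponents are classical downstream values completing the continuity
    constraint exp_width + exp_depth + exp_velocity = 1.
    """

    width_max: float = 1.0     # m at the outlet
    depth_max: float = 1.0     # m at the outlet
    velocity_max: float = 1.0  # m/s at the outlet
    exp_width: float = 0.5
    exp_depth: float = 0.4
    exp_velocity: float = 0.1

    def __post_init__(self):
        if min(self.width_max, self.depth_max, self.velocity_max) <= 0:
            raise ValueError("outlet width/depth/velocity must be positive")
        s = self.exp_width + self.exp_depth + self.exp_velocity
        if abs(s - 1.0) > 1e-9:
            raise ValueError(
                f"Leopold exponents must sum to 1 (continuity); got {s}"
            )


def _outlet_area(level: LevelNetwork) -> np.ndarray:
    """Drainage area of the outlet draining each node (pixel units)."""
    n = level.n_nodes
    recv = level.receiver
    out = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        p = i
        chain = []
        while out[p] < 0 and recv[p] >= 0:
            chain.append(p)
            p = int(recv[p])
        o = out[p] if out[p] >= 0 else p
        out[p] = o
        for c in chain:
            out[c] = o
    return level.A[out]


def hydraulic_geometry(
    level: LevelNetwork, params: HydraulicParams = HydraulicParams()
) -> pd.DataFrame:
    """Width, depth and velocity per node of an RN or AG network.

    At each catchment's outlet the three quantities equal their ``*_max``
    values; elsewhere they decay as powers of relative drainage area.
    """
    if level.level not in ("RN", "AG"):
        raise ValueError("hydraulic geometry applies to RN or AG levels")
    ratio = level.A.astype(float) / _outlet_area(level).astype(float)
    return pd.DataFrame(
        {
            "width": params.width_max * ratio**params.exp_width,
            "depth": params.depth_max * ratio**params.exp_depth,
            "velocity": params.velocity_max * ratio**params.exp_velocity,
        }
    )


def distance_to_outlet(level: LevelNetwork) -> np.ndarray:
    """Along-network distance (m) from each node to its outlet."""
    n = level.n_nodes
    recv = level.receiver
    dist = np.full(n, np.nan)
    order = []
    indeg = level.indegree.copy()
    stack = list(np.nonzero(indeg == 0)[0])
    # downstream topological order, then fill from outlets upstream
    while stack:
        i = stack.pop()
        order.append(i)
        r = int(recv[i])
        if r >= 0:
            indeg[r] -= 1
            if indeg[r] == 0:
                stack.append(r)
    for i in reversed(order):
        r = int(recv[i])
        dist[i] = 0.0 if r < 0 else dist[r] + level.L[i]
    return dist


def path_lengths(level: LevelNetwork, pairwise: bool = True):
    """Distances to the outlet and, optionally, all pairwise network
    distances.

    The network distance between two nodes sums their distances down to
    the lowest common downstream node; nodes in different catchments are
    unreachable (infinite distance).  Returns ``(dist_to_outlet,
    pairwise_matrix)``; the matrix is None when ``pairwise`` is False.
    """
    dto = distance_to_outlet(level)
    if not pairwise:
        return dto, None
    n = level.n_nodes
    recv = level.receiver
    # downstream node sets for junction search
    paths: list[dict[int, float]] = []
    outlet_of = np.empty(n, dtype=np.int64)
    for i in range(n):
        p = i
        d = {}
        while True:
            d[p] = dto[p]
            r = int(recv[p])
            if r < 0:
                outlet_of[i] = p
                break
            p = r
        paths.append(d)
    D = np.full((n, n), np.inf)
    for i in range(n):
        D[i, i] = 0.0
        for j in range(i + 1, n):
            if outlet_of[i] != outlet_of[j]:
                continue
            common = paths[i].keys() & paths[j].keys()
            d_junction = max(paths[i][c] for c in common)
            D[i, j] = D[j, i] = (dto[i] - d_junction) + (dto[j] - d_junction)
    return dto, D
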