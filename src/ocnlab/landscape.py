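"""Slopes, elevations and catchment partitioning derived from an OCN.

The slope-area relationship s ~ A**(gamma-1) fixes channel slopes up to the
slope of the outlet; walking upstream and accumulating s_i * L_i elevation
drops (L_i is the outgoing-link length, sqrt(2)*cellsize on diagonals)
yields the elevation field subsumed by the network, up to the outlet
elevation.  Strictly the relationship holds only for the channeled portion
of the domain; applying it to every pixel is a first approximation, and an
optional threshold caps hillslope-pixel slopes at the value attained at the
channelization threshold, making hillslope elevation profiles linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annealing import OCNState
from .lattice import FlowField, link_lengths, validate_tree

__all__ = [
    "ElevationField",
    "CatchmentPartition",
    "assign_slopes",
    "compute_elevation",
    "catchments",
]


@dataclass
class ElevationField:
    slope: np.ndarray  # dimensionless, per pixel
    z: np.ndarray      # meters, per pixel
    slope0: float
    z0: float


@dataclass
class CatchmentPartition:
    """Per-pixel outlet identifier (the CM aggregation level)."""

    label: np.ndarray  # int64, outlet pixel index per pixel

    def counts(self) -> dict[int, int]:
        vals, cnt = np.unique(self.label, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, cnt)}


def _downstream_order(flow: FlowField) -> np.ndarray:
    """Pixel indices ordered so that every receiver precedes its sources."""
    n = flow.lattice.n_pixels
    recv = flow.receiver
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        r = int(recv[i])
        if r >= 0:
            children[r].append(i)
    order = []
    stack = list(flow.lattice.outlets)
    while stack:
        j = stack.pop()
        order.append(j)
        stack.extend(children[j])
    return np.array(order, dtype=np.int64)


def catchments(flow: FlowField) -> CatchmentPartition:
    """Label each pixel with the outlet its downstream walk reaches."""
    report = validate_tree(flow)
    if not report:
        raise ValueError(f"invalid flow field: {report.issues}")
    n = flow.lattice.n_pixels
    label = np.full(n, -1, dtype=np.int64)
    for o in flow.lattice.outlets:
        label[o] = o
    for i in _downstream_order(flow):
        if label[i] < 0:
            label[i] = label[flow.receiver[i]]
    return CatchmentPartition(label)


def assign_slopes(
    state: OCNState,
    slope0: float = 0.01,
    channel_threshold: int | None = None,
) -> np.ndarray:
    """Per-pixel slopes from the slope-area relationship.

    ``s_i = slope0 * (A_i / A_outlet)**(gamma - 1)`` with A_outlet the
    drainage area of the outlet draining pixel i; outlet pixels carry
    slope0 itself.  If ``channel_threshold`` (pixels) is given, hillslope
    pixels (A < threshold) use the slope attained at the threshold instead
    of their own area, keeping hillslope elevation profiles linear.
    """
    if slope0 <= 0:
        raise ValueError("slope0 must be positive")
    A = state.areas.A.astype(float)
    part = catchments(state.flow)
    A_out = state.areas.A[part.label].astype(float)
    A_eff = A if channel_threshold is None else np.maximum(A, channel_threshold)
    slope = slope0 * (A_eff / A_out) ** (state.gamma - 1.0)
    slope[list(state.lattice.outlets)] = slope0
    return slope


def compute_elevation(
    state: OCNState, slopes: np.ndarray, z0: float = 0.0
) -> ElevationField:
    """Elevations by upstream accumulation of per-link drops s_i * L_i.

    Every outlet sits at ``z0``; each pixel sits above its receiver by its
    slope times its outgoing-link length.
    """
    slopes = np.asarray(slopes, dtype=float)
    n = state.lattice.n_pixels
    if slopes.shape != (n,):
        raise ValueError("slope field shape does not match lattice")
    if np.any(slopes <= 0):
        raise ValueError("slopes must be positive")
    L = link_lengths(state.flow)
    recv = state.flow.receiver
    z = np.full(n, np.nan)
    for o in state.lattice.outlets:
        z[o] = z0
    for i in _downstream_order(state.flow):
        if recv[i] >= 0:
            z[i] = z[recv[i]] + slopes[i] * L[i]
    slope0 = float(slopes[state.lattice.outlets[0]])
    return ElevationField(slope=slopes, z=z, slope0=slope0, z0=float(z0))
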