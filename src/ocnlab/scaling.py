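"""Scaling-law statistics of channel networks.

Real rivers and their OCN analogues share a family of power laws: the
exceedance probability of drainage areas P(A >= a) ~ a**(-beta) with beta
around 0.43, and Hack's law L ~ A**h (h around 0.57) linking the longest
upstream channelized length to drainage area.  Fits are ordinary least
squares on log10 axes over distinct points, restricted to areas below a
cutoff (default 2% of the lattice size) to avoid finite-size effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .aggregation import LevelNetwork
from .annealing import OCNState
from .lattice import AreaField

__all__ = [
    "ScalingFit",
    "CUTOFF_FRACTION",
    "exceedance",
    "fit_power_law",
    "exceedance_exponent",
    "hack_exponent",
    "upstream_lengths",
    "flow_upstream_lengths",
]

#: default fit cutoff: areas up to this fraction of the lattice size
CUTOFF_FRACTION = 0.02


@dataclass
class ScalingFit:
    exponent: float
    intercept: float  # log10-space
    r2: float
    fit_range: tuple[float, float]
    n_points: int


def exceedance(areas: AreaField | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distinct drainage areas a and P(A >= a) over lattice pixels."""
    A = areas.A if isinstance(areas, AreaField) else np.asarray(areas)
    a = np.unique(A)
    # P(A >= a) via the complementary cumulative count
    counts = np.searchsorted(np.sort(A), a, side="left")
    P = 1.0 - counts / A.size
    return a.astype(float), P


def fit_power_law(
    x: np.ndarray, y: np.ndarray, x_max: Optional[float] = None
) -> ScalingFit:
    """OLS fit of log10 y against log10 x, optionally truncated at x_max."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = (x > 0) & (y > 0)
    if x_max is not None:
        keep &= x <= x_max
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 positive points inside the cutoff")
    res = stats.linregress(np.log10(x), np.log10(y))
    return ScalingFit(
        exponent=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        fit_range=(float(x.min()), float(x.max())),
        n_points=int(x.size),
    )


def exceedance_exponent(
    areas: AreaField | np.ndarray,
    n_pixels: int,
    cutoff_fraction: float = CUTOFF_FRACTION,
) -> ScalingFit:
    """Fit P(A >= a) ~ a**(-beta); the returned exponent is the OLS slope
    (so beta is its negation)."""
    a, P = exceedance(areas)
    return fit_power_law(a, P, x_max=cutoff_fraction * n_pixels)


def upstream_lengths(rn: LevelNetwork) -> np.ndarray:
    """Longest upstream channelized path length (m) ending at each RN node.

    Dynamic programming over the RN forest: a node's length is the maximum
    over upstream neighbors of their length plus their outgoing-link
    length (sqrt(2)*cellsize on diagonals); sources have length 0.
    """
    n = rn.n_nodes
    recv = rn.receiver
    indeg = rn.indegree.copy()
    L_up = np.zeros(n, dtype=float)
    stack = list(np.nonzero(indeg == 0)[0])
    while stack:
        i = stack.pop()
        r = int(recv[i])
        if r < 0:
            continue
        L_up[r] = max(L_up[r], L_up[i] + rn.L[i])
        indeg[r] -= 1
        if indeg[r] == 0:
            stack.append(r)
    return L_up


def flow_upstream_lengths(flow) -> np.ndarray:
    """Longest upstream flow-path length (m) from the drainage divide to
    each pixel, over the full flow-direction tree."""
    from .lattice import link_lengths

    n = flow.lattice.n_pixels
    recv = flow.receiver
    step = link_lengths(flow)
    indeg = np.bincount(recv[recv >= 0], minlength=n)
    L_up = np.zeros(n, dtype=float)
    stack = list(np.nonzero(indeg == 0)[0])
    while stack:
        i = stack.pop()
        r = int(recv[i])
        if r < 0:
            continue
        L_up[r] = max(L_up[r], L_up[i] + step[i])
        indeg[r] -= 1
        if indeg[r] == 0:
            stack.append(r)
    return L_up


def hack_exponent(
    state: OCNState,
    rn: LevelNetwork,
    cutoff_fraction: float = CUTOFF_FRACTION,
) -> ScalingFit:
    """Hack's-law fit of log L against log A over the channelized pixels.

    L is the mainstream length: the longest upstream flow path from the
    drainage divide, measured on the full flow-direction tree
    (sqrt(2)*cellsize on diagonal steps) and sampled at the RN nodes, so
    the aggregation threshold sets the lower end of the fitted range.
    Areas above the cutoff fraction of the lattice are excluded as
    finite-size affected.
    """
    if rn.n_nodes < 3:
        raise ValueError("RN network too small for a Hack fit")
    L = flow_upstream_lengths(state.flow)[rn.to_fd]
    A = rn.A.astype(float)
    return fit_power_law(A, L, x_max=cutoff_fraction * state.lattice.n_pixels)
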