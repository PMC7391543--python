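"""Deterministic metapopulation dynamics on the RN-level network.

Discrete-time model of an invading riverine species: local growth at each
network node follows the Beverton-Holt map

    growth(P) = r * P / (1 + (r - 1) * P / K)

and at every step a fraction g of the local population disperses, moving
downstream with probability p_d and upstream with probability p_u = 1 - p_d.
Individuals moving upstream from a node split among its upstream neighbors
in proportion to their drainage areas (weights Y).  The update is
synchronous:

    P_i(t+1) = growth(P_i(t))
               + g * [ p_d * sum_j w_ji P_j
                       + p_u * Y_i * P_{recv(i)}
                       - (p_d * D_i + p_u * U_i) * P_i ]

where w is the downstream RN adjacency, D_i / U_i flag the existence of a
downstream / upstream connection, and the movement terms redistribute but
never create or destroy individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .aggregation import LevelNetwork
from .geometry import distance_to_outlet

__all__ = [
    "MetapopParams",
    "MetapopState",
    "DispersalStructure",
    "MetapopTrajectory",
    "dispersal_weights",
    "step",
    "initialize_invasion",
    "run",
]


@dataclass
class MetapopParams:
    """Demographic and movement parameters.

    ``K`` is the per-node carrying capacity, conventionally built as
    ``kappa * width`` (kappa individuals per meter of channel width).
    """

    K: np.ndarray
    r: float = 1.05
    g: float = 0.1
    p_d: float = 0.5

    def __post_init__(self):
        self.K = np.asarray(self.K, dtype=float)
        if np.any(self.K <= 0):
            raise ValueError("carrying capacities must be positive")
        if self.r <= 0:
            raise ValueError("fecundity r must be positive")
        if not 0.0 <= self.g <= 1.0:
            raise ValueError("mobility g must lie in [0, 1]")
        if not 0.0 <= self.p_d <= 1.0:
            raise ValueError("p_d must lie in [0, 1]")

    @property
    def p_u(self) -> float:
        return 1.0 - self.p_d

    @classmethod
    def from_widths(
        cls, widths: np.ndarray, kappa: float = 10.0, **kwargs
    ) -> "MetapopParams":
        return cls(K=kappa * np.asarray(widths, dtype=float), **kwargs)


@dataclass
class MetapopState:
    P: np.ndarray
    t: int = 1

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)


@dataclass
class DispersalStructure:
    """Connectivity indicators and upstream split weights of an RN network."""

    W: sp.csr_matrix
    D: np.ndarray  # 1 if the node has a downstream connection
    U: np.ndarray  # 1 if the node has at least one upstream connection
    Y: np.ndarray  # upstream split weight; weights of siblings sum to 1
    receiver: np.ndarray


def dispersal_weights(rn: LevelNetwork) -> DispersalStructure:
    """Build movement structure; Y_i = A_i / sum of sibling areas."""
    recv = rn.receiver
    indeg = rn.indegree
    D = (recv >= 0).astype(float)
    U = (indeg > 0).astype(float)
    A = rn.A.astype(float)
    sibling_sum = np.zeros(rn.n_nodes)
    np.add.at(sibling_sum, recv[recv >= 0], A[recv >= 0])
    Y = np.zeros(rn.n_nodes)
    has_recv = recv >= 0
    Y[has_recv] = A[has_recv] / sibling_sum[recv[has_recv]]
    return DispersalStructure(W=rn.W, D=D, U=U, Y=Y, receiver=recv.copy())


def beverton_holt(P: np.ndarray, r: float, K: np.ndarray) -> np.ndarray:
    return r * P / (1.0 + (r - 1.0) * P / K)


def movement(
    P: np.ndarray, params: MetapopParams, disp: DispersalStructure
) -> np.ndarray:
    """Net movement term (the bracketed g-part of the update); sums to zero."""
    p_d, p_u = params.p_d, params.p_u
    inflow_down = disp.W.T @ P  # from upstream neighbors moving downstream
    recv = disp.receiver
    P_recv = np.where(recv >= 0, P[np.clip(recv, 0, None)], 0.0)
    inflow_up = disp.Y * P_recv
    outflow = (p_d * disp.D + p_u * disp.U) * P
    return params.g * (p_d * inflow_down + p_u * inflow_up - outflow)


def step(
    state: MetapopState, params: MetapopParams, disp: DispersalStructure
) -> MetapopState:
    """One synchronous update of the metapopulation."""
    P = state.P
    if P.shape != params.K.shape:
        raise ValueError("population vector does not match the network size")
    if np.any(P < 0):
        raise ValueError("negative populations are not allowed")
    P_next = beverton_holt(P, params.r, params.K) + movement(P, params, disp)
    return MetapopState(P=P_next, t=state.t + 1)


def initialize_invasion(rn: LevelNetwork) -> MetapopState:
    """Seed one individual at the node farthest (along the network) from
    its outlet; ties break to the lowest node index."""
    dto = distance_to_outlet(rn)
    f = int(np.argmax(dto))
    P = np.zeros(rn.n_nodes)
    P[f] = 1.0
    return MetapopState(P=P, t=1)


@dataclass
class MetapopTrajectory:
    """Per-node population series; row t-1 holds the state at time t."""

    P: np.ndarray            # (t_max, n)
    times: np.ndarray        # 1..t_max
    params: MetapopParams
    onset_node: int

    @property
    def totals(self) -> np.ndarray:
        return self.P.sum(axis=1)

    def equilibrium_time(
        self, node: Optional[int] = None, t_ref: int = 800, frac: float = 0.99
    ) -> int:
        """First time step at which the (node or total) population reaches
        ``frac`` of its value at the reference time ``t_ref``."""
        series = self.totals if node is None else self.P[:, node]
        ref = series[t_ref - 1]
        hits = np.nonzero(series >= frac * ref)[0]
        return int(self.times[hits[0]])

    def to_frame(self) -> pd.DataFrame:
        """Long-format (t, node, P) table."""
        t_max, n = self.P.shape
        return pd.DataFrame(
            {
                "t": np.repeat(self.times, n),
                "node": np.tile(np.arange(n), t_max),
                "P": self.P.ravel(),
            }
        )


def run(
    rn: LevelNetwork,
    params: MetapopParams,
    t_max: int = 800,
    P0: Optional[MetapopState] = None,
) -> MetapopTrajectory:
    """Iterate the model for ``t_max`` steps from the invasion seed."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    disp = dispersal_weights(rn)
    state = P0 if P0 is not None else initialize_invasion(rn)
    onset = int(np.argmax(state.P))
    out = np.empty((t_max, rn.n_nodes))
    out[0] = state.P
    for k in range(1, t_max):
        state = step(state, params, disp)
        out[k] = state.P
    return MetapopTrajectory(
        P=out, times=np.arange(1, t_max + 1), params=params, onset_node=onset
    )
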