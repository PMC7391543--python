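"""Lattice geometry and flow-field primitives.

A flow field assigns to every non-outlet pixel of a regular lattice a single
downstream receiver among its 8 (Moore) neighbors, forming a spanning forest
rooted at the outlet pixels.  Drainage area at a pixel is the number of pixels
whose downstream walk passes through it (itself included); it satisfies the
linear relation (I - W^T) A = 1 where W is the sparse downstream adjacency
matrix of the forest.

Pixel indexing is column-major over (x, y): pixel (x, y) has flat index
``x * dimY + y``.  The center of pixel (x, y) sits at
``((x + 0.5) * cellsize, (y + 0.5) * cellsize)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "LatticeSpec",
    "FlowField",
    "AreaField",
    "TreeReport",
    "build_lattice",
    "initial_flow",
    "validate_tree",
    "accumulate_areas",
    "adjacency_matrix",
    "downstream_path",
    "neighbor_table",
    "link_lengths",
]

_SIDES = ("N", "E", "S", "W")

# Moore neighborhood offsets: (dx, dy, diagonal?)
_OFFSETS = (
    (-1, -1, True), (-1, 0, False), (-1, 1, True),
    (0, -1, False), (0, 1, False),
    (1, -1, True), (1, 0, False), (1, 1, True),
)


@dataclass(frozen=True)
class LatticeSpec:
    """Regular lattice with declared outlet pixels.

    Attributes
    ----------
    dimX, dimY : int
        Lattice dimensions in pixels.
    cellsize : float
        Side length of a pixel in meters.
    periodic : bool
        If True, neighborhoods wrap around the lattice boundaries.
    outlets : tuple[int, ...]
        Flat indices of the outlet pixels; all lie on the perimeter.
    """

    dimX: int
    dimY: int
    cellsize: float = 1.0
    periodic: bool = False
    outlets: tuple[int, ...] = field(default=())

    @property
    def n_pixels(self) -> int:
        return self.dimX * self.dimY

    def index(self, x: int, y: int) -> int:
        return x * self.dimY + y

    def xy(self, i: int) -> tuple[int, int]:
        return divmod(int(i), self.dimY)

    def coords(self, idx: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Center coordinates (meters) of the given pixels (default: all)."""
        if idx is None:
            idx = np.arange(self.n_pixels)
        idx = np.asarray(idx)
        x, y = np.divmod(idx, self.dimY)
        return (x + 0.5) * self.cellsize, (y + 0.5) * self.cellsize

    def is_perimeter(self, i: int) -> bool:
        x, y = self.xy(i)
        return x in (0, self.dimX - 1) or y in (0, self.dimY - 1)

    @property
    def outlet_mask(self) -> np.ndarray:
        m = np.zeros(self.n_pixels, dtype=bool)
        m[list(self.outlets)] = True
        return m


def _perimeter_pixel(dimX: int, dimY: int, side: str, pos: int) -> int:
    """Flat index of the perimeter pixel at 0-based ``pos`` along ``side``.

    For the southern (y=0) and northern (y=dimY-1) sides, ``pos`` is the x
    coordinate; for the western (x=0) and eastern (x=dimX-1) sides it is y.
    """
    side = side.upper()
    if side == "S":
        x, y = pos, 0
    elif side == "N":
        x, y = pos, dimY - 1
    elif side == "W":
        x, y = 0, pos
    elif side == "E":
        x, y = dimX - 1, pos
    else:
        raise ValueError(f"unknown side {side!r}; expected one of {_SIDES}")
    if not (0 <= x < dimX and 0 <= y < dimY):
        raise ValueError(f"outlet position {pos} out of range for side {side}")
    return x * dimY + y


def _perimeter_indices(dimX: int, dimY: int) -> list[int]:
    out = []
    for x in range(dimX):
        for y in range(dimY):
            if x in (0, dimX - 1) or y in (0, dimY - 1):
                out.append(x * dimY + y)
    return out


def build_lattice(
    dimX: int,
    dimY: int,
    cellsize: float = 1.0,
    outlets: str | Sequence = (("S", 0),),
    periodic: bool = False,
) -> LatticeSpec:
    """Construct and validate a lattice specification.

    Parameters
    ----------
    outlets
        Either the string ``"all"`` (every perimeter pixel becomes an
        outlet), or a sequence whose elements are ``(side, pos)`` pairs
        (side in N/E/S/W, 0-based position along that side) or flat pixel
        indices.  Default: a single outlet at the south-west corner.
    """
    dimX, dimY = int(dimX), int(dimY)
    if dimX < 1 or dimY < 1 or dimX * dimY < 4:
        raise ValueError("lattice must have at least 4 pixels")
    if cellsize <= 0:
        raise ValueError("cellsize must be positive")
    n = dimX * dimY
    if isinstance(outlets, str):
        if outlets.lower() != "all":
            raise ValueError(f"unknown outlet token {outlets!r}")
        idx = _perimeter_indices(dimX, dimY)
    else:
        idx = []
        for o in outlets:
            if isinstance(o, (int, np.integer)):
                i = int(o)
                if not (0 <= i < n):
                    raise ValueError(f"outlet index {i} out of range")
            else:
                side, pos = o
                i = _perimeter_pixel(dimX, dimY, side, int(pos))
            idx.append(i)
    if not idx:
        raise ValueError("at least one outlet is required")
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate outlet pixels")
    lat = LatticeSpec(dimX, dimY, float(cellsize), bool(periodic), tuple(idx))
    for i in idx:
        if not lat.is_perimeter(i):
            raise ValueError(f"outlet pixel {i} is not on the lattice perimeter")
    return lat


def neighbor_table(lattice: LatticeSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moore neighbors of every pixel.

    Returns ``(nbr, count, diag)``: an (N, 8) array of neighbor indices
    padded with -1, the per-pixel neighbor count, and a parallel boolean
    array flagging diagonal neighbors.  Non-periodic boundary pixels have 5
    neighbors (3 at corners); periodic lattices wrap to 8 everywhere.
    """
    dimX, dimY = lattice.dimX, lattice.dimY
    n = lattice.n_pixels
    nbr = np.full((n, 8), -1, dtype=np.int64)
    diag = np.zeros((n, 8), dtype=bool)
    count = np.zeros(n, dtype=np.int64)
    for x in range(dimX):
        for y in range(dimY):
            i = x * dimY + y
            k = 0
            for dx, dy, d in _OFFSETS:
                nx, ny = x + dx, y + dy
                if lattice.periodic:
                    nx %= dimX
                    ny %= dimY
                elif not (0 <= nx < dimX and 0 <= ny < dimY):
                    continue
                j = nx * dimY + ny
                if j == i:
                    continue
                nbr[i, k] = j
                diag[i, k] = d
                k += 1
            count[i] = k
    return nbr, count, diag


def _is_diagonal_step(lattice: LatticeSpec, i: int, j: int) -> bool:
    xi, yi = lattice.xy(i)
    xj, yj = lattice.xy(j)
    dx, dy = abs(xi - xj), abs(yi - yj)
    if lattice.periodic:
        dx = min(dx, lattice.dimX - dx)
        dy = min(dy, lattice.dimY - dy)
    return dx == 1 and dy == 1


def link_lengths(flow: "FlowField") -> np.ndarray:
    """Length (meters) of each pixel's outgoing link.

    Diagonal links measure sqrt(2) * cellsize; outlet pixels, which have no
    outgoing link, are charged one lateral cellsize so that total channel
    length over a straight unit-cell network equals the pixel count.
    """
    lat = flow.lattice
    lengths = np.full(lat.n_pixels, lat.cellsize, dtype=float)
    recv = flow.receiver
    for i in range(lat.n_pixels):
        r = recv[i]
        if r >= 0 and _is_diagonal_step(lat, i, int(r)):
            lengths[i] = np.sqrt(2.0) * lat.cellsize
    return lengths


@dataclass
class FlowField:
    """Per-pixel downstream receiver; -1 marks outlet pixels."""

    lattice: LatticeSpec
    receiver: np.ndarray  # int64, shape (N,)

    def __post_init__(self):
        self.receiver = np.asarray(self.receiver, dtype=np.int64)
        if self.receiver.shape != (self.lattice.n_pixels,):
            raise ValueError("receiver array shape does not match lattice")

    def copy(self) -> "FlowField":
        return FlowField(self.lattice, self.receiver.copy())


@dataclass
class AreaField:
    """Per-pixel drainage area in pixel units (integers >= 1)."""

    A: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=np.int64)


@dataclass
class TreeReport:
    valid: bool
    issues: list[str]

    def __bool__(self) -> bool:
        return self.valid


def _nearest_outlets(lattice: LatticeSpec) -> np.ndarray:
    """Nearest outlet (Manhattan metric, lowest index on ties) per pixel."""
    n = lattice.n_pixels
    x, y = np.divmod(np.arange(n), lattice.dimY)
    best = np.full(n, -1, dtype=np.int64)
    best_d = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    for o in lattice.outlets:
        ox, oy = lattice.xy(o)
        d = np.abs(x - ox) + np.abs(y - oy)
        better = d < best_d
        best[better] = o
        best_d[better] = d[better]
    return best


def _outlet_side(lattice: LatticeSpec, o: int) -> str:
    x, y = lattice.xy(o)
    if y == 0:
        return "S"
    if y == lattice.dimY - 1:
        return "N"
    if x == 0:
        return "W"
    return "E"


def initial_flow(lattice: LatticeSpec, style: str = "I") -> FlowField:
    """Deterministic feasible initial spanning forest.

    Two styles are provided.  ``"I"`` routes each pixel straight toward the
    side its nearest outlet sits on, then along that side to the outlet.
    ``"V"`` routes diagonally toward the nearest outlet until aligned with
    it, then straight, producing two flow diagonals converging on the
    outlet.  Both strictly decrease the Manhattan distance to the assigned
    outlet at every step and therefore always produce a valid forest.
    """
    if style not in ("I", "V"):
        raise ValueError(f"unknown initial-flow style {style!r}")
    n = lattice.n_pixels
    recv = np.full(n, -1, dtype=np.int64)
    nearest = _nearest_outlets(lattice)
    outlet_set = set(lattice.outlets)
    for i in range(n):
        if i in outlet_set:
            continue
        o = int(nearest[i])
        x, y = lattice.xy(i)
        ox, oy = lattice.xy(o)
        sx = int(np.sign(ox - x))
        sy = int(np.sign(oy - y))
        if style == "I":
            side = _outlet_side(lattice, o)
            if side in ("S", "N"):
                step = (0, sy) if y != oy else (sx, 0)
            else:
                step = (sx, 0) if x != ox else (0, sy)
        else:  # V: diagonal first, then straight
            if sx != 0 and sy != 0:
                step = (sx, sy)
            elif sx != 0:
                step = (sx, 0)
            else:
                step = (0, sy)
        recv[i] = lattice.index(x + step[0], y + step[1])
    flow = FlowField(lattice, recv)
    report = validate_tree(flow)
    if not report:
        raise RuntimeError(
            f"style {style!r} produced an invalid flow field: {report.issues}"
        )
    return flow


def validate_tree(flow: FlowField) -> TreeReport:
    """Check the spanning-forest invariants of a flow field.

    Valid iff outlets have no receiver, every non-outlet pixel points to a
    Moore neighbor, and following receivers from any pixel reaches an
    outlet without revisiting a pixel (no cycles).
    """
    lat = flow.lattice
    n = lat.n_pixels
    recv = flow.receiver
    issues: list[str] = []
    outlet_mask = lat.outlet_mask
    if np.any(recv[outlet_mask] != -1):
        issues.append("an outlet pixel has a receiver")
    non_outlet = ~outlet_mask
    bad = non_outlet & ((recv < 0) | (recv >= n))
    if np.any(bad):
        issues.append(
            f"{int(bad.sum())} non-outlet pixel(s) lack a valid receiver"
        )
    else:
        nbr, count, _ = neighbor_table(lat)
        for i in np.nonzero(non_outlet)[0]:
            r = recv[i]
            if r == i:
                issues.append(f"pixel {i} is its own receiver")
                break
            if r not in nbr[i, : count[i]]:
                issues.append(f"receiver of pixel {i} is not a neighbor")
                break
    if not issues:
        # reverse BFS from outlets: all pixels reachable <=> no cycles
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            r = recv[i]
            if r >= 0:
                children[int(r)].append(i)
        seen = np.zeros(n, dtype=bool)
        stack = list(lat.outlets)
        seen[stack] = True
        while stack:
            j = stack.pop()
            for c in children[j]:
                if not seen[c]:
                    seen[c] = True
                    stack.append(c)
        if not np.all(seen):
            issues.append(
                f"{int((~seen).sum())} pixel(s) do not drain to an outlet (cycle)"
            )
    return TreeReport(valid=not issues, issues=issues)


def accumulate_areas(flow: FlowField) -> AreaField:
    """Drainage areas by upstream-to-downstream accumulation.

    Equivalent to solving (I - W^T) A = 1; each pixel carries one unit plus
    everything drained by its upstream neighbors.
    """
    report = validate_tree(flow)
    if not report:
        raise ValueError(f"invalid flow field: {report.issues}")
    n = flow.lattice.n_pixels
    recv = flow.receiver
    A = np.ones(n, dtype=np.int64)
    indeg = np.bincount(recv[recv >= 0], minlength=n)
    stack = list(np.nonzero(indeg == 0)[0])
    while stack:
        i = stack.pop()
        r = int(recv[i])
        if r >= 0:
            A[r] += A[i]
            indeg[r] -= 1
            if indeg[r] == 0:
                stack.append(r)
    return AreaField(A)


def adjacency_matrix(flow: FlowField) -> sp.csr_matrix:
    """Sparse downstream adjacency W with W[i, j] = 1 iff receiver(i) = j."""
    n = flow.lattice.n_pixels
    src = np.nonzero(flow.receiver >= 0)[0]
    dst = flow.receiver[src]
    return sp.csr_matrix(
        (np.ones(len(src)), (src, dst)), shape=(n, n), dtype=np.int8
    )


def downstream_path(flow: FlowField, pixel: int) -> list[int]:
    """Pixels visited walking downstream from ``pixel`` to its outlet, inclusive."""
    n = flow.lattice.n_pixels
    pixel = int(pixel)
    if not (0 <= pixel < n):
        raise IndexError(f"pixel index {pixel} out of range")
    path = [pixel]
    p = pixel
    while flow.receiver[p] >= 0:
        p = int(flow.receiver[p])
        path.append(p)
        if len(path) > n:
            raise RuntimeError("cycle encountered while walking downstream")
    return path
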