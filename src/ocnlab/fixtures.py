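"""Small deterministic flow fields used in examples and tests.

``chain4``
    A 1x4 column draining straight down to a single outlet; the unique
    spanning tree of that lattice, with areas 1, 2, 3, 4 along the chain.
``yjunction``
    A 2x2 lattice where two head pixels (areas 1 and 1) join at a
    confluence (area 3) that drains into the outlet (area 4).
``grid8``
    A synthetic single-outlet 8x8 field (not an OCN; illustrative only):
    pixels below the main diagonal flow west, pixels above flow south, and
    the diagonal itself channels everything south-west into the corner
    outlet, producing triple junctions and diagonal links.
"""

from __future__ import annotations

import numpy as np

from .lattice import FlowField, build_lattice

__all__ = ["fixtures", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("chain4", "yjunction", "grid8")


def _chain4() -> FlowField:
    lat = build_lattice(1, 4, outlets=(("S", 0),))
    recv = np.array([-1, 0, 1, 2], dtype=np.int64)
    return FlowField(lat, recv)


def _yjunction() -> FlowField:
    lat = build_lattice(2, 2, outlets=(("S", 0),))
    # indices: (0,0)=0 outlet, (0,1)=1 confluence, (1,0)=2 head, (1,1)=3 head
    recv = np.array([-1, 0, 1, 1], dtype=np.int64)
    return FlowField(lat, recv)


def _grid8() -> FlowField:
    lat = build_lattice(8, 8, outlets=(("S", 0),))
    recv = np.full(64, -1, dtype=np.int64)
    for x in range(8):
        for y in range(8):
            if x == 0 and y == 0:
                continue
            if x == y:
                nxt = (x - 1, y - 1)  # diagonal main stem
            elif x > y:
                nxt = (x - 1, y)      # west toward the diagonal
            else:
                nxt = (x, y - 1)      # south toward the diagonal
            recv[lat.index(x, y)] = lat.index(*nxt)
    return FlowField(lat, recv)


def fixtures(name: str) -> FlowField:
    """Return a named fixture flow field."""
    builders = {"chain4": _chain4, "yjunction": _yjunction, "grid8": _grid8}
    try:
        return builders[name]()
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
        ) from None
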