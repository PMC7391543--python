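import numpy as np
import pandas as pd
import pytest

import ocnlab as o
from ocnlab.aggregation import LevelNetwork
from ocnlab.annealing import AnnealingSchedule, OCNState, energy
from ocnlab.lattice import accumulate_areas, build_lattice, neighbor_table


@pytest.fixture
def chain4():
    return o.fixtures("chain4")


@pytest.fixture
def yjunction():
    return o.fixtures("yjunction")


@pytest.fixture
def grid8():
    return o.fixtures("grid8")


def make_state(flow, gamma=0.5) -> OCNState:
    """Wrap a flow field into an OCNState without annealing."""
    areas = accumulate_areas(flow)
    return OCNState(
        flow=flow,
        areas=areas,
        gamma=gamma,
        H=energy(areas, gamma),
        schedule=AnnealingSchedule(n_iter=1, T0=1.0),
        history=pd.DataFrame(),
    )


def make_level(receiver, A, L=None, level="RN", cellsize=1.0) -> LevelNetwork:
    """Hand-built level network for junction fixtures."""
    receiver = np.asarray(receiver, dtype=np.int64)
    n = len(receiver)
    A = np.asarray(A, dtype=np.int64)
    L = np.ones(n) * cellsize if L is None else np.asarray(L, dtype=float)
    lat = build_lattice(max(2, n), 2, cellsize=cellsize, outlets=(("S", 0),))
    return LevelNetwork(
        level=level, lattice=lat, receiver=receiver, A=A,
        X=np.arange(n, dtype=float), Y=np.zeros(n), L=L,
        to_fd=np.arange(n, dtype=np.int64),
    )


def random_flow(dim_x, dim_y, seed, n_moves=200, outlets=(("S", 0),)):
    """Random valid flow field: legal random rewires from the I state."""
    lat = build_lattice(dim_x, dim_y, outlets=outlets)
    flow = o.initial_flow(lat, style="I")
    rng = np.random.default_rng(seed)
    nbr, count, _ = neighbor_table(lat)
    non_outlet = np.setdiff1d(np.arange(lat.n_pixels), np.array(lat.outlets))
    for _ in range(n_moves):
        i = int(rng.choice(non_outlet))
        opts = [int(j) for j in nbr[i, : count[i]] if j != flow.receiver[i]]
        j = int(rng.choice(opts))
        if not o.creates_loop(flow, i, j):
            flow.receiver[i] = j
    return flow


@pytest.fixture(scope="session")
def small_ocn():
    """A 15x15 annealed OCN shared across tests."""
    lat = build_lattice(15, 15, outlets=(("S", 7),))
    return o.anneal(o.initial_flow(lat), schedule=AnnealingSchedule(seed=7))


@pytest.fixture(scope="session")
def net20():
    """The worked-example network: 20x20 lattice, 500 m cells, outlet at
    position 3 on the southern side, aggregated at 5 pixels (1.25 km2)."""
    lat = build_lattice(20, 20, cellsize=500.0, outlets=(("S", 3),))
    state = o.anneal(o.initial_flow(lat), schedule=AnnealingSchedule(seed=1))
    rn = o.extract_rn(state, 5)
    return state, rn
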