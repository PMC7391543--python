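"""Readers and writers for standard text formats.

Flow fields and level networks round-trip through CSV node tables plus a
JSON metadata sidecar; sparse adjacency matrices go to MatrixMarket
coordinate files; rasters (elevation, subcatchment and catchment labels) go
to ESRI ASCII grids.  A flat YAML run configuration drives the command-line
pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io as sio
import yaml
from pydantic import BaseModel, ConfigDict

from .aggregation import LevelNetwork
from .annealing import AnnealingSchedule, OCNState
from .lattice import (
    AreaField,
    FlowField,
    LatticeSpec,
    adjacency_matrix,
    build_lattice,
)

__all__ = [
    "RunConfig",
    "save_ocn",
    "load_ocn",
    "write_asc",
    "read_asc",
    "write_level_tables",
    "read_level_table",
]


class RunConfig(BaseModel):
    """Flat configuration for the full pipeline; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid")

    dimX: int = 20
    dimY: int = 20
    cellsize: float = 1.0
    periodic: bool = False
    outlet_side: str = "S"
    outlet_pos: int = 0
    all_perimeter_outlets: bool = False
    seed: int = 0
    gamma: float = 0.5
    n_iter: Optional[int] = None
    T0: Optional[float] = None
    cooling_rate: float = 1.0
    no_cooling_fraction: float = 0.0
    slope0: float = 0.01
    z0: float = 0.0
    thr_a_pixels: Optional[float] = None
    thr_a_m2: Optional[float] = None
    width_max: float = 1.0
    depth_max: float = 1.0
    velocity_max: float = 1.0
    exp_width: float = 0.5
    exp_depth: float = 0.4
    exp_velocity: float = 0.1
    r: float = 1.05
    g: float = 0.1
    p_d: float = 0.5
    kappa: float = 10.0
    t_max: int = 800

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def threshold_pixels(self, lattice: LatticeSpec) -> float:
        """Aggregation threshold in pixels; m2 input converts via cellsize."""
        if self.thr_a_pixels is not None:
            return float(self.thr_a_pixels)
        if self.thr_a_m2 is not None:
            return float(self.thr_a_m2) / lattice.cellsize**2
        return 0.002 * lattice.n_pixels


def _lattice_meta(lat: LatticeSpec) -> dict:
    return {
        "dimX": lat.dimX,
        "dimY": lat.dimY,
        "cellsize": lat.cellsize,
        "periodic": lat.periodic,
        "outlets": list(map(int, lat.outlets)),
    }


def _lattice_from_meta(meta: dict) -> LatticeSpec:
    return build_lattice(
        meta["dimX"],
        meta["dimY"],
        cellsize=meta["cellsize"],
        outlets=meta["outlets"],
        periodic=meta["periodic"],
    )


def save_ocn(state: OCNState, directory) -> None:
    """Persist an annealed OCN: metadata JSON, FD node CSV, sparse W, history."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    lat = state.lattice
    sched = state.schedule
    meta = {
        "lattice": _lattice_meta(lat),
        "gamma": state.gamma,
        "H": state.H,
        "schedule": {
            "n_iter": sched.n_iter,
            "T0": sched.T0,
            "cooling_rate": sched.cooling_rate,
            "no_cooling_fraction": sched.no_cooling_fraction,
            "record_every": sched.record_every,
            "seed": sched.seed,
        },
    }
    (d / "ocn_meta.json").write_text(json.dumps(meta, indent=1))
    X, Y = lat.coords()
    pd.DataFrame(
        {
            "pixel": np.arange(lat.n_pixels),
            "x": X,
            "y": Y,
            "receiver": state.flow.receiver,
            "is_outlet": lat.outlet_mask.astype(int),
            "A": state.areas.A,
        }
    ).to_csv(d / "fd_nodes.csv", index=False, float_format="%.17g")
    sio.mmwrite(d / "W_fd.mtx", adjacency_matrix(state.flow).tocoo())
    state.history.to_csv(d / "history.csv", index=False, float_format="%.17g")


def load_ocn(directory) -> OCNState:
    d = Path(directory)
    meta_path = d / "ocn_meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(
            f"{meta_path} not found: run the 'generate' step first"
        )
    meta = json.loads(meta_path.read_text())
    lat = _lattice_from_meta(meta["lattice"])
    nodes = pd.read_csv(d / "fd_nodes.csv")
    flow = FlowField(lat, nodes["receiver"].to_numpy(dtype=np.int64))
    areas = AreaField(nodes["A"].to_numpy(dtype=np.int64))
    history = pd.read_csv(d / "history.csv", float_precision="round_trip")
    sched = AnnealingSchedule(**meta["schedule"])
    return OCNState(
        flow=flow,
        areas=areas,
        gamma=meta["gamma"],
        H=meta["H"],
        schedule=sched,
        history=history,
    )


def write_asc(
    path, values: np.ndarray, lattice: LatticeSpec, nodata: float = -9999,
    fmt: str = "%.6g",
) -> None:
    """Write a per-pixel array as an ESRI ASCII grid.

    Rows run north to south; our column-major pixel order is reshaped
    accordingly.
    """
    vals = np.asarray(values, dtype=float).reshape(lattice.dimX, lattice.dimY)
    grid = vals.T[::-1, :]  # (row = north..south, col = west..east)
    header = (
        f"ncols {lattice.dimX}\n"
        f"nrows {lattice.dimY}\n"
        "xllcorner 0.0\n"
        "yllcorner 0.0\n"
        f"cellsize {lattice.cellsize}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid, fmt=fmt)


def read_asc(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid back to per-pixel (column-major) order."""
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        key, val = line.split()
        header[key] = float(val)
    grid = np.loadtxt(lines[6:])
    grid = np.atleast_2d(grid)
    values = grid[::-1, :].T.reshape(-1)
    return values, header


def _level_frame(level: LevelNetwork, extra: Optional[pd.DataFrame] = None):
    df = pd.DataFrame(
        {
            "node": np.arange(level.n_nodes),
            "pixel": level.to_fd,
            "x": level.X,
            "y": level.Y,
            "receiver": level.receiver,
            "A": level.A,
            "L": level.L,
        }
    )
    if level.stream_order is not None:
        df["streamOrder"] = level.stream_order
    if level.to_rn is not None:
        df["to_rn"] = level.to_rn
    if extra is not None:
        df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
    return df


def write_level_tables(
    directory,
    rn: Optional[LevelNetwork] = None,
    ag: Optional[LevelNetwork] = None,
    elevation=None,
    sc_labels: Optional[np.ndarray] = None,
    cm_labels: Optional[np.ndarray] = None,
    lattice: Optional[LatticeSpec] = None,
    rn_extra: Optional[pd.DataFrame] = None,
    ag_extra: Optional[pd.DataFrame] = None,
) -> None:
    """Write per-level node tables, adjacency, rasters and edge lists."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    if rn is not None:
        _level_frame(rn, rn_extra).to_csv(d / "rn_nodes.csv", index=False)
        sio.mmwrite(d / "W_rn.mtx", rn.W.tocoo())
    if ag is not None:
        _level_frame(ag, ag_extra).to_csv(d / "ag_nodes.csv", index=False)
        sio.mmwrite(d / "W_ag.mtx", ag.W.tocoo())
        src = np.nonzero(ag.receiver >= 0)[0]
        pd.DataFrame(
            {"src": src, "dst": ag.receiver[src], "length": ag.L[src]}
        ).to_csv(d / "ag_edges.tsv", sep="\t", index=False)
    if elevation is not None:
        if lattice is None:
            raise ValueError("lattice required to write rasters")
        write_asc(d / "elevation.asc", elevation.z, lattice)
        pd.DataFrame({"slope": elevation.slope}).to_csv(
            d / "slopes.csv", index=False
        )
    if sc_labels is not None:
        if lattice is None:
            raise ValueError("lattice required to write rasters")
        write_asc(d / "sc.asc", sc_labels, lattice, fmt="%d")
    if cm_labels is not None:
        if lattice is None:
            raise ValueError("lattice required to write rasters")
        write_asc(d / "cm.asc", cm_labels, lattice, fmt="%d")


def read_level_table(directory, level: str, lattice: LatticeSpec) -> LevelNetwork:
    """Rebuild a LevelNetwork from a written node table."""
    d = Path(directory)
    name = {"RN": "rn_nodes.csv", "AG": "ag_nodes.csv"}[level.upper()]
    path = d / name
    if not path.exists():
        raise FileNotFoundError(
            f"{path} not found: run the 'aggregate' step first"
        )
    df = pd.read_csv(path)
    net = LevelNetwork(
        level=level.upper(),
        lattice=lattice,
        receiver=df["receiver"].to_numpy(dtype=np.int64),
        A=df["A"].to_numpy(dtype=np.int64),
        X=df["x"].to_numpy(dtype=float),
        Y=df["y"].to_numpy(dtype=float),
        L=df["L"].to_numpy(dtype=float),
        to_fd=df["pixel"].to_numpy(dtype=np.int64),
        to_rn=(
            df["to_rn"].to_numpy(dtype=np.int64) if "to_rn" in df else None
        ),
        stream_order=(
            df["streamOrder"].to_numpy(dtype=np.int64)
            if "streamOrder" in df
            else None
        ),
    )
    return net
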