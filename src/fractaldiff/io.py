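"""CSV/JSON readers and writers for MSD series, trajectories and fits.

Dialect: comma-separated, required header, '.' decimal, UTF-8.  Numbers
are written with 12 significant digits so a write/read round trip is
lossless at that precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .series import MSDSeries
from .synthetic import TrajectoryTable

__all__ = [
    "read_msd_csv",
    "write_msd_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
]

_FLOAT_FMT = "%.12g"


def read_msd_csv(path: Union[str, Path]) -> MSDSeries:
    """Read an MSD series from CSV with columns ``time,msd[,dim]``."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InvalidInputError(f"cannot parse {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "time" not in cols or "msd" not in cols:
        raise InvalidInputError(
            f"{path}: need header columns 'time' and 'msd', got {list(df.columns)}")
    dim = 2
    if "dim" in cols:
        dims = df[cols["dim"]].unique()
        if len(dims) != 1:
            raise InvalidInputError(f"{path}: mixed 'dim' values {dims}")
        dim = int(dims[0])
    bad = df[cols["time"]].isna() | df[cols["msd"]].isna()
    if bad.any():
        line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
        raise InvalidInputError(f"{path}: non-numeric or missing value at line {line}")
    return MSDSeries(times=df[cols["time"]].to_numpy(float),
                     msd=df[cols["msd"]].to_numpy(float),
                     dimensionality=dim)


def write_msd_csv(series: MSDSeries, path: Union[str, Path]) -> None:
    df = pd.DataFrame({"time": series.times, "msd": series.msd,
                       "dim": series.dimensionality})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory_csv(path: Union[str, Path]) -> TrajectoryTable:
    """Read a 2D trajectory from CSV with columns ``time,x,y``."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise InvalidInputError(f"cannot parse {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    for need in ("time", "x", "y"):
        if need not in cols:
            raise InvalidInputError(
                f"{path}: need header columns time,x,y, got {list(df.columns)}")
    return TrajectoryTable(
        times=df[cols["time"]].to_numpy(float),
        positions=df[[cols["x"], cols["y"]]].to_numpy(float))


def write_trajectory_csv(traj: TrajectoryTable, path: Union[str, Path]) -> None:
    df = pd.DataFrame({"time": traj.times,
                       "x": traj.positions[:, 0],
                       "y": traj.positions[:, 1]})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
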