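"""Tabular text I/O for fields and structured configs for patterns.

Displacement volumes/planes and traction fields travel as header-bearing
tab-separated text; rows may come in any order, the grid is reassembled
from the coordinates and validated for completeness.  Traction patterns
are YAML with explicit units (lengths in um, forces in uN - converted to
the internal pN on read).
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fields import (PN_PER_UN, DisplacementField, GridSpec, TractionField)
from .simulate import HertzPatch, TractionPattern

__all__ = [
    "read_displacement",
    "write_displacement",
    "read_traction",
    "write_traction",
    "read_pattern",
    "write_pattern",
    "config_hash",
]

_DISP_COLS = ["x_um", "y_um", "z_um", "ux_um", "uy_um", "uz_um"]
_TRAC_COLS = ["x_um", "y_um", "tx_Pa", "ty_Pa", "tz_Pa"]


def _unique_axis(values: np.ndarray, name: str) -> np.ndarray:
    axis = np.unique(values)
    if len(axis) > 1:
        steps = np.diff(axis)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9 * abs(steps[0])):
            raise ValueError(f"{name} coordinates are not regularly spaced")
    return axis


def _grid_indices(values: np.ndarray, axis: np.ndarray, name: str) -> np.ndarray:
    if len(axis) > 1:
        d = axis[1] - axis[0]
        idx = np.round((values - axis[0]) / d).astype(int)
        if not np.allclose(axis[0] + idx * d, values, rtol=1e-9,
                           atol=1e-6 * abs(d)):
            raise ValueError(f"{name} coordinates do not sit on the grid")
    else:
        idx = np.zeros(len(values), dtype=int)
    return idx


def write_displacement(path: str | Path, fieldv: DisplacementField) -> None:
    """Write a displacement field as TSV (columns x_um .. uz_um)."""
    g = fieldv.grid
    X, Y = g.xy_mesh()
    rows = []
    u = fieldv.u if g.is_volume else fieldv.u[None]
    for iz, z in enumerate(g.z):
        rows.append(np.column_stack([
            X.ravel(), Y.ravel(), np.full(X.size, z),
            u[iz].reshape(-1, 3),
        ]))
    data = np.vstack(rows)
    header = "\t".join(_DISP_COLS)
    np.savetxt(path, data, fmt="%.15g", delimiter="\t", header=header,
               comments="")


def read_displacement(path: str | Path) -> DisplacementField:
    """Read a displacement field written by :func:`write_displacement`.

    Rows may be shuffled; the grid is reassembled from the coordinates.
    Missing or duplicate nodes raise with the offending coordinate named.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _DISP_COLS:
        raise ValueError(
            f"unexpected displacement header {list(df.columns)}; "
            f"expected {_DISP_COLS}")
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValueError("non-numeric or non-finite cells in displacement file")
    xs = _unique_axis(df["x_um"].to_numpy(), "x")
    ys = _unique_axis(df["y_um"].to_numpy(), "y")
    zs = _unique_axis(df["z_um"].to_numpy(), "z")
    nx, ny, nz = len(xs), len(ys), len(zs)
    if len(df) != nx * ny * nz:
        raise ValueError(
            f"incomplete grid: {len(df)} rows cannot fill a "
            f"{nx} x {ny} x {nz} lattice")
    ix = _grid_indices(df["x_um"].to_numpy(), xs, "x")
    iy = _grid_indices(df["y_um"].to_numpy(), ys, "y")
    iz = _grid_indices(df["z_um"].to_numpy(), zs, "z")
    u = np.full((nz, ny, nx, 3), np.nan)
    u[iz, iy, ix] = df[["ux_um", "uy_um", "uz_um"]].to_numpy()
    missing = np.argwhere(~np.isfinite(u[..., 0]))
    if len(missing):
        mz, my, mx = missing[0]
        raise ValueError(
            f"incomplete grid: node (x={xs[mx]}, y={ys[my]}, z={zs[mz]}) "
            "is missing")
    dx = xs[1] - xs[0]
    if nz > 1:
        grid = GridSpec(nx=nx, ny=ny, dx=dx, dy=ys[1] - ys[0], nz=nz,
                        dz=zs[1] - zs[0], origin=(xs[0], ys[0], zs[0]))
        return DisplacementField(grid, u)
    grid = GridSpec(nx=nx, ny=ny, dx=dx, dy=ys[1] - ys[0],
                    origin=(xs[0], ys[0], 0.0), plane_depth=float(zs[0]))
    return DisplacementField(grid, u[0])


def write_traction(path: str | Path, traction: TractionField) -> None:
    """Write a surface traction field as TSV (columns x_um .. tz_Pa)."""
    X, Y = traction.grid.xy_mesh()
    data = np.column_stack([X.ravel(), Y.ravel(),
                            traction.t.reshape(-1, 3)])
    np.savetxt(path, data, fmt="%.15g", delimiter="\t",
               header="\t".join(_TRAC_COLS), comments="")


def read_traction(path: str | Path) -> TractionField:
    """Read a traction field written by :func:`write_traction`."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != _TRAC_COLS:
        raise ValueError(
            f"unexpected traction header {list(df.columns)}; "
            f"expected {_TRAC_COLS}")
    xs = _unique_axis(df["x_um"].to_numpy(), "x")
    ys = _unique_axis(df["y_um"].to_numpy(), "y")
    nx, ny = len(xs), len(ys)
    if len(df) != nx * ny:
        raise ValueError(
            f"incomplete grid: {len(df)} rows cannot fill {nx} x {ny}")
    ix = _grid_indices(df["x_um"].to_numpy(), xs, "x")
    iy = _grid_indices(df["y_um"].to_numpy(), ys, "y")
    t = np.full((ny, nx, 3), np.nan)
    t[iy, ix] = df[["tx_Pa", "ty_Pa", "tz_Pa"]].to_numpy()
    if not np.all(np.isfinite(t)):
        raise ValueError("incomplete traction grid")
    grid = GridSpec(nx=nx, ny=ny, dx=xs[1] - xs[0], dy=ys[1] - ys[0],
                    origin=(xs[0], ys[0], 0.0))
    return TractionField(grid, t)


_PATTERN_KEYS = {"name", "units", "patches"}
_PATCH_KEYS = {"x0_um", "y0_um", "a_um", "Qx_uN", "Qy_uN", "Qz_uN"}


def write_pattern(path: str | Path, pattern: TractionPattern) -> None:
    """Serialize a pattern as YAML (forces in uN, lengths in um)."""
    doc = {
        "name": pattern.name,
        "units": {"length": "um", "force": "uN"},
        "patches": [
            {
                "x0_um": float(p.center[0]),
                "y0_um": float(p.center[1]),
                "a_um": float(p.radius),
                "Qx_uN": float(p.load[0] / PN_PER_UN),
                "Qy_uN": float(p.load[1] / PN_PER_UN),
                "Qz_uN": float(p.load[2] / PN_PER_UN),
            }
            for p in pattern.patches
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_pattern(path: str | Path) -> TractionPattern:
    """Read a YAML pattern definition; unknown keys are errors."""
    doc = yaml.safe_load(Path(path).read_text())
    extra = set(doc) - _PATTERN_KEYS
    if extra:
        raise ValueError(f"unknown pattern config keys: {sorted(extra)}")
    units = doc.get("units", {})
    if units.get("length", "um") != "um" or units.get("force", "uN") != "uN":
        raise ValueError(f"unsupported units declaration: {units}")
    patches = []
    for entry in doc.get("patches", []):
        extra = set(entry) - _PATCH_KEYS
        if extra:
            raise ValueError(f"unknown patch keys: {sorted(extra)}")
        patches.append(HertzPatch(
            center=(float(entry["x0_um"]), float(entry["y0_um"])),
            radius=float(entry["a_um"]),
            load=(float(entry.get("Qx_uN", 0.0)) * PN_PER_UN,
                  float(entry.get("Qy_uN", 0.0)) * PN_PER_UN,
                  float(entry.get("Qz_uN", 0.0)) * PN_PER_UN),
        ))
    return TractionPattern(patches, name=doc.get("name", ""))


def config_hash(obj) -> str:
    """Short deterministic hash of a config-like mapping, for provenance."""
    canon = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
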