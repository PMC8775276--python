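"""Sampling grids and field containers shared by all reconstruction routines.

Conventions
-----------
* The substrate occupies the half-space ``z > 0``; the free surface on which
  traction acts is the plane ``z = 0``, with outward normal along ``-z``.
* All lengths are in micrometres, stresses in Pascal.  Forces obtained by
  integrating traction over area are therefore in Pa*um^2 = pN; conversion
  to microNewton (1 uN = 1e6 pN) happens only at the I/O boundary.
* Volume arrays are indexed ``[iz, iy, ix, component]`` and plane arrays
  ``[iy, ix, component]``, 0-based, node-centred.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "GridSpec",
    "DisplacementField",
    "TractionField",
    "StressTensorField",
    "PN_PER_UN",
]

#: piconewton per micronewton (internal force unit -> I/O force unit)
PN_PER_UN = 1.0e6


@dataclass(frozen=True)
class GridSpec:
    """A regular sampling lattice: a plane (``nz == 1``) or a cuboid volume.

    Parameters
    ----------
    nx, ny : int
        Node counts along x and y (>= 4).
    dx, dy : float
        In-plane spacings in um.  The two must be equal; the anisotropy of
        confocal imaging is expressed only through ``dz``.
    nz : int
        Node count along z; 1 marks a plane field, volumes need >= 3.
    dz : float
        Spacing along z in um (typically larger than ``dx``).
    origin : tuple of float
        Position of node (0, 0, 0) in um.  Volume grids used for surface
        traction read-off must start at z = 0.
    plane_depth : float
        Depth h (um) of the observation plane for plane grids.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    nz: int = 1
    dz: float = 0.0
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    plane_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 4:
            raise ValueError("grids need nx, ny >= 4")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("spacings must be positive")
        if abs(self.dx - self.dy) > 1e-9 * max(self.dx, self.dy):
            raise ValueError("dx and dy must be equal")
        if self.nz < 1:
            raise ValueError("nz must be >= 1")
        if self.nz > 1:
            if self.nz < 3:
                raise ValueError("volume grids need nz >= 3")
            if self.dz <= 0:
                raise ValueError("volume grids need dz > 0")
        if self.plane_depth < 0:
            raise ValueError("plane_depth must be >= 0 (inside the substrate)")

    # -- geometry -----------------------------------------------------------

    @property
    def is_volume(self) -> bool:
        return self.nz > 1

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + self.dx * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + self.dy * np.arange(self.ny)

    @property
    def z(self) -> np.ndarray:
        if self.is_volume:
            return self.origin[2] + self.dz * np.arange(self.nz)
        return np.array([self.plane_depth])

    def xy_mesh(self) -> Tuple[np.ndarray, np.ndarray]:
        """(ny, nx) meshes of node x and y coordinates."""
        return np.meshgrid(self.x, self.y, indexing="xy")

    def wavenumbers(self) -> Tuple[np.ndarray, np.ndarray]:
        """(ny, nx) meshes of angular wavenumbers for the DFT on this grid."""
        kx = 2.0 * np.pi * np.fft.fftfreq(self.nx, d=self.dx)
        ky = 2.0 * np.pi * np.fft.fftfreq(self.ny, d=self.dy)
        return np.meshgrid(kx, ky, indexing="xy")

    def surface(self) -> "GridSpec":
        """The z = 0 surface plane of a volume grid (or self for planes)."""
        if not self.is_volume:
            return self
        return GridSpec(
            nx=self.nx, ny=self.ny, dx=self.dx, dy=self.dy,
            origin=(self.origin[0], self.origin[1], 0.0), plane_depth=0.0,
        )

    def with_spacing(self, dx: float, dz: float | None = None) -> "GridSpec":
        """Same node counts at different spacings (z scaled alongside xy)."""
        if dz is None:
            dz = self.dz * dx / self.dx if self.is_volume else 0.0
        return replace(self, dx=dx, dy=dx, dz=dz)


def _check_field(grid: GridSpec, arr: np.ndarray, trailing: Tuple[int, ...],
                 name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    want = ((grid.nz, grid.ny, grid.nx) if grid.is_volume
            else (grid.ny, grid.nx)) + trailing
    if arr.shape != want:
        raise ValueError(f"{name} shape {arr.shape} does not match grid {want}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    return arr


@dataclass
class DisplacementField:
    """Displacement vectors (um) sampled on a plane or volume grid."""

    grid: GridSpec
    u: np.ndarray  # (ny, nx, 3) or (nz, ny, nx, 3)

    def __post_init__(self) -> None:
        self.u = _check_field(self.grid, self.u, (3,), "u")

    @property
    def kind(self) -> str:
        return "volume" if self.grid.is_volume else "plane"

    def mean_magnitude(self) -> float:
        """<||u||>: mean displacement-vector magnitude over all nodes."""
        return float(np.mean(np.linalg.norm(self.u, axis=-1)))

    def surface_layer(self) -> "DisplacementField":
        """The z = 0 layer of a volume field as a plane field."""
        if not self.grid.is_volume:
            return self
        if abs(self.grid.origin[2]) > 1e-9:
            raise ValueError("volume grid does not include the z = 0 surface")
        return DisplacementField(self.grid.surface(), self.u[0])


@dataclass
class TractionField:
    """Surface traction vectors (Pa) on a z = 0 plane grid."""

    grid: GridSpec
    t: np.ndarray  # (ny, nx, 3)

    def __post_init__(self) -> None:
        if self.grid.is_volume:
            raise ValueError("traction lives on a surface grid")
        self.t = _check_field(self.grid, self.t, (3,), "traction")

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.t, axis=-1)

    def tangential_magnitude(self) -> np.ndarray:
        return np.hypot(self.t[..., 0], self.t[..., 1])


@dataclass
class StressTensorField:
    """Symmetric Cauchy stress tensors (Pa) per volume node."""

    grid: GridSpec
    sigma: np.ndarray  # (nz, ny, nx, 3, 3)

    def __post_init__(self) -> None:
        if not self.grid.is_volume:
            raise ValueError("stress tensor fields live on volume grids")
        self.sigma = _check_field(self.grid, self.sigma, (3, 3), "sigma")

    def symmetry_error(self) -> float:
        """Largest |sigma_ij - sigma_ji| over the field."""
        return float(np.max(np.abs(self.sigma - np.swapaxes(self.sigma, -1, -2))))
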