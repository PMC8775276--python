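"""Linear isotropic half-space elasticity: material law and Green's functions.

The substrate is modelled as a homogeneous, isotropic, linearly elastic
half-space ``z > 0`` with Young's modulus ``E`` and Poisson ratio ``nu``.
Surface traction ``tau`` and substrate displacement ``u`` are linked by the
Boussinesq-Cerruti convolution

    u(x, y, z) = \\iint G(x - x', y - y', z) . tau(x', y') dx' dy',

where ``G`` is the classical point-force (Boussinesq) Green's function.
This module provides ``G`` in real space, its tangential 2x2 surface form in
Fourier space (the 2D FTTC kernel), and the full 3x3 Fourier-space kernel
evaluated at depth ``z`` (the 2.5D FTTC kernel), plus the constitutive
conversions stress <-> displacement gradient and stress -> surface traction.

Fourier convention: ``f~(k) = \\iint f(x) exp(-i k.x) dx``, so the
convolution theorem reads ``u~(k, z) = G~(k, z) . tau~(k)`` with no extra
2*pi factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import StressTensorField, TractionField

__all__ = [
    "ElasticMaterial",
    "DEFAULT_MATERIAL",
    "greens_real",
    "greens_fourier_2d",
    "greens_fourier_25d",
    "stress_from_gradient",
    "traction_from_stress_surface",
]


@dataclass(frozen=True)
class ElasticMaterial:
    """Linear isotropic elastic material.

    Parameters
    ----------
    youngs_modulus : float
        E in Pa; must be positive.  Typical TFM substrates (PAA, PDMS) are
        around 10 kPa.
    poisson_ratio : float
        nu, dimensionless, in [0, 0.5].  TFM gels are nearly incompressible
        (nu close to 0.5); the direct method's constitutive law additionally
        needs nu < 0.5 because its dilatational term carries 1/(1 - 2 nu).
    """

    youngs_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5]")

    @property
    def shear_modulus(self) -> float:
        """mu = E / (2 (1 + nu)) in Pa."""
        return self.youngs_modulus / (2.0 * (1.0 + self.poisson_ratio))


#: 10 kPa, nu = 0.49: a typical nearly incompressible TFM substrate that is
#: still valid for the direct method's 1/(1 - 2 nu) term.
DEFAULT_MATERIAL = ElasticMaterial(youngs_modulus=1.0e4, poisson_ratio=0.49)


def greens_real(x, y, z, material: ElasticMaterial) -> np.ndarray:
    """Boussinesq half-space Green's function G(x, y, z), shape (..., 3, 3).

    Entry ``G[i, j]`` is the displacement component ``i`` at (x, y, z) caused
    by a unit point force along ``j`` applied at the surface origin.  Units:
    um displacement per (Pa um^2) of force, i.e. 1/(Pa um).

    Inputs broadcast; ``z`` must be >= 0 (inside the substrate) and the
    evaluation point must not be the singular origin r = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z < 0 lies outside the substrate half-space")
    r = np.sqrt(x * x + y * y + z * z)
    if np.any(r == 0):
        raise ValueError("Green's function is singular at r = 0")

    nu = material.poisson_ratio
    E = material.youngs_modulus
    pref = (1.0 + nu) / (2.0 * np.pi * E)
    rz = r + z
    # common factor of the tangential-tangential quadratic terms
    q = (2.0 * r * (nu * r + z) + z * z) / (r**3 * rz**2)
    a = (2.0 * (1.0 - nu) * r + z) / (r * rz)
    c = (1.0 - 2.0 * nu) / (r * rz)
    zr3 = z / r**3

    G = np.empty(np.broadcast(x, y, z).shape + (3, 3), dtype=float)
    G[..., 0, 0] = a + q * x * x
    G[..., 0, 1] = q * x * y
    G[..., 0, 2] = x * zr3 - c * x
    G[..., 1, 0] = q * x * y
    G[..., 1, 1] = a + q * y * y
    G[..., 1, 2] = y * zr3 - c * y
    G[..., 2, 0] = c * x + x * zr3
    G[..., 2, 1] = c * y + y * zr3
    G[..., 2, 2] = 2.0 * (1.0 - nu) / r + z * z / r**3
    return pref * G


def greens_fourier_2d(kx, ky, material: ElasticMaterial) -> np.ndarray:
    """Tangential surface Green's function in Fourier space, shape (..., 2, 2).

    This is the 2D FTTC kernel

        G~2D(k) = 1/(mu k^3) [[(1-nu) k^2 + nu ky^2,  -nu kx ky],
                              [-nu kx ky,  (1-nu) k^2 + nu kx^2]],

    the z -> 0 tangential limit of the 2.5D kernel.  Units um/Pa.  The zero
    mode k = 0 is undefined (the operator has no inverse there); callers
    decide the zero-mode policy.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    k = np.hypot(kx, ky)
    if np.any(k == 0):
        raise ValueError("zero mode k = 0 is undefined for the Fourier kernel")
    nu = material.poisson_ratio
    mu = material.shear_modulus
    k2 = k * k
    G = np.empty(np.broadcast(kx, ky).shape + (2, 2), dtype=float)
    G[..., 0, 0] = (1.0 - nu) * k2 + nu * ky * ky
    G[..., 0, 1] = -nu * kx * ky
    G[..., 1, 0] = -nu * kx * ky
    G[..., 1, 1] = (1.0 - nu) * k2 + nu * kx * kx
    return G / (mu * k2 * k)[..., None, None]


def greens_fourier_25d(kx, ky, z, material: ElasticMaterial) -> np.ndarray:
    """Full 3x3 Fourier-space Green's function at depth z, complex (..., 3, 3).

    Closed form obtained from the Boussinesq-Cerruti potential route:

        G~(k, z) = e^{-k z} / (2 mu k^3) *
            [[2 k^2 - (2 nu + k z) kx^2, -(2 nu + k z) kx ky,  (1 - 2 nu - k z) i k kx],
             [-(2 nu + k z) kx ky, 2 k^2 - (2 nu + k z) ky^2,  (1 - 2 nu - k z) i k ky],
             [-(1 - 2 nu + k z) i k kx, -(1 - 2 nu + k z) i k ky, 2 (1 - nu) k^2 + k^3 z]]

    The imaginary off-diagonal entries couple tangential load to normal
    displacement and vice versa; at z = 0 the matrix is Hermitian and its
    tangential block reduces to :func:`greens_fourier_2d`.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise ValueError("z < 0 lies outside the substrate half-space")
    k = np.hypot(kx, ky)
    if np.any(k == 0):
        raise ValueError("zero mode k = 0 is undefined for the Fourier kernel")
    nu = material.poisson_ratio
    mu = material.shear_modulus
    kz = k * z
    k2 = k * k
    tt = 2.0 * nu + kz          # tangential-tangential depth factor
    G = np.empty(np.broadcast(kx, ky, z).shape + (3, 3), dtype=complex)
    G[..., 0, 0] = 2.0 * k2 - tt * kx * kx
    G[..., 0, 1] = -tt * kx * ky
    G[..., 0, 2] = (1.0 - 2.0 * nu - kz) * 1j * k * kx
    G[..., 1, 0] = -tt * kx * ky
    G[..., 1, 1] = 2.0 * k2 - tt * ky * ky
    G[..., 1, 2] = (1.0 - 2.0 * nu - kz) * 1j * k * ky
    G[..., 2, 0] = -(1.0 - 2.0 * nu + kz) * 1j * k * kx
    G[..., 2, 1] = -(1.0 - 2.0 * nu + kz) * 1j * k * ky
    G[..., 2, 2] = 2.0 * (1.0 - nu) * k2 + k2 * kz
    return G * (np.exp(-kz) / (2.0 * mu * k2 * k))[..., None, None]


def stress_from_gradient(grad_u: np.ndarray,
                         material: ElasticMaterial) -> np.ndarray:
    """Hooke's law: stress from the displacement-gradient tensor.

    ``grad_u[..., i, j]`` holds du_i/dx_j (dimensionless).  Returns the
    symmetric Cauchy stress

        sigma = mu (grad_u + grad_u^T) + 2 mu nu / (1 - 2 nu) tr(grad_u) I

    in Pa.  Incompressible material (nu = 0.5) is rejected: the dilatational
    modulus diverges, and only the exactly divergence-free limit would keep
    the product finite, which sampled data cannot guarantee.
    """
    nu = material.poisson_ratio
    if nu >= 0.5:
        raise ValueError(
            "nu = 0.5 (incompressible) is not usable here: the dilatational "
            "term 2 nu/(1 - 2 nu) tr(grad u) diverges; use nu < 0.5"
        )
    grad_u = np.asarray(grad_u, dtype=float)
    if grad_u.shape[-2:] != (3, 3):
        raise ValueError("grad_u must have trailing shape (3, 3)")
    mu = material.shear_modulus
    sym = grad_u + np.swapaxes(grad_u, -1, -2)
    tr = np.trace(grad_u, axis1=-2, axis2=-1)
    eye = np.eye(3)
    return mu * sym + (2.0 * mu * nu / (1.0 - 2.0 * nu)) * tr[..., None, None] * eye


def traction_from_stress_surface(stress: StressTensorField) -> TractionField:
    """Surface traction tau = -(sigma_13, sigma_23, sigma_33) at z = 0.

    The sign follows from the outward surface normal pointing along -z.
    The volume grid must start at the surface (origin z = 0); the traction
    is read off the first z-layer without extrapolation.
    """
    if abs(stress.grid.origin[2]) > 1e-9:
        raise ValueError(
            "stress volume does not contain the z = 0 surface layer "
            f"(grid starts at z = {stress.grid.origin[2]})"
        )
    s0 = stress.sigma[0]  # (ny, nx, 3, 3)
    t = -s0[..., :, 2]
    return TractionField(stress.grid.surface(), t.copy())
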