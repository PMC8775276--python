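"""Divergence correction: projecting a measured stress field toward force balance.

A static, externally unloaded elastic body satisfies the Cauchy momentum
balance d(sigma_ij)/dx_j = 0 at every point, so the stress computed from a
*measured* displacement field acquires divergence only through measurement
noise.  Following the hydrodynamic analogy (each row of the stress tensor
is a vector field that must be solenoidal, like an incompressible flow),
the correction iterates, for a fixed number of cycles:

    1. split sigma into its three row vector fields,
    2. replace each by its nearest divergence-free field (discrete
       least-squares projection, centred-difference divergence enforced at
       interior nodes),
    3. reassemble the tensor,
    4. symmetrize, sigma <- (w + w^T)/2.

Symmetrization partially re-introduces divergence, which is why the loop
runs for several cycles; it is an alternating projection between the
"solenoidal rows" and "symmetric" subspaces and converges to their
intersection.  Twenty cycles are the fixed default.

The projection itself solves  min ||v' - v||^2  s.t.  D v' = 0, with D the
centred-difference divergence at interior nodes (boundary nodes carry no
constraint), via the normal equations of the constraint system: an exact
sparse factorization, cached per grid shape.  A faster approximate
spectral backend (Helmholtz projection on a reflectively padded grid) is
available for exploratory use; the exact backend is the reference.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import StressTensorField
from .results import DivergenceReport

__all__ = [
    "stress_divergence",
    "interior_divergence_norm",
    "project_divergence_free",
    "correct_stress",
]


def stress_divergence(stress: StressTensorField) -> np.ndarray:
    """Residual body-force density d(sigma_ij)/dx_j, shape (nz, ny, nx, 3).

    Centred two-point differences at interior nodes, one-sided two-point
    at the boundary.
    """
    g = stress.grid
    s = stress.sigma
    div = np.zeros(s.shape[:3] + (3,))
    # spatial axis j = x, y, z -> array axis 2, 1, 0
    for j, (d, ax) in enumerate(((g.dx, 2), (g.dy, 1), (g.dz, 0))):
        div += np.gradient(s[..., :, j], d, axis=ax, edge_order=1)
    return div


def interior_divergence_norm(stress: StressTensorField) -> float:
    """Plain L2 norm of the stress divergence over interior nodes."""
    div = stress_divergence(stress)
    return float(np.linalg.norm(div[1:-1, 1:-1, 1:-1]))


@lru_cache(maxsize=8)
def _divergence_system(shape: tuple[int, int, int],
                       spacings: tuple[float, float, float]):
    """Sparse centred-difference divergence operator on interior nodes and
    a factorization of D D^T for the least-squares projection.

    ``shape`` is (nz, ny, nx); ``spacings`` is (dz, dy, dx).  The flattened
    vector field is ordered [node, component] with node = C-order (z, y, x)
    and component = (x, y, z).
    """
    nz, ny, nx = shape
    dz, dy, dx = spacings
    n_nodes = nz * ny * nx
    node = np.arange(n_nodes).reshape(nz, ny, nx)
    centers = node[1:-1, 1:-1, 1:-1].ravel()
    n_rows = centers.size
    rows, cols, data = [], [], []
    strides = {  # component -> (node-index stride, spacing)
        0: (1, dx),        # x neighbours are adjacent in the last axis
        1: (nx, dy),
        2: (ny * nx, dz),
    }
    for comp, (stride, d) in strides.items():
        for sign in (+1, -1):
            rows.append(np.arange(n_rows))
            cols.append(3 * (centers + sign * stride) + comp)
            data.append(np.full(n_rows, sign / (2.0 * d)))
    D = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_rows, 3 * n_nodes),
    )
    DDT = (D @ D.T).tocsc()
    try:
        solve = spla.factorized(DDT)
    except RuntimeError:  # singular normal matrix: fall back to iterative
        solve = None
    return D, solve


def project_divergence_free(v: np.ndarray,
                            spacings: tuple[float, float, float],
                            backend: str = "exact") -> np.ndarray:
    """Nearest divergence-free field to ``v`` in the node-wise least-squares
    sense, the discrete divergence vanishing at every interior node.

    Parameters
    ----------
    v : ndarray, shape (nz, ny, nx, 3)
        Vector field on a volume grid.
    spacings : (dz, dy, dx)
        Grid spacings in um.
    backend : "exact" or "spectral"
        "exact" solves the constrained least-squares problem via the
        cached sparse factorization and is the reference; "spectral"
        performs a Helmholtz (transverse) projection on a reflectively
        padded grid - fast, but it enforces a different (global, periodic)
        notion of divergence-freeness and is only approximate here.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 4 or v.shape[-1] != 3:
        raise ValueError("v must have shape (nz, ny, nx, 3)")
    if min(v.shape[:3]) < 3:
        raise ValueError("volume too small: every axis needs >= 3 nodes")
    if backend == "spectral":
        return _project_spectral(v, spacings)
    if backend != "exact":
        raise ValueError("backend must be 'exact' or 'spectral'")
    D, solve = _divergence_system(v.shape[:3], tuple(spacings))
    b = D @ v.ravel()
    if solve is not None:
        corr = D.T @ solve(b)
    else:  # singular normal matrix: minimum-norm correction via LSMR
        corr = spla.lsmr(D, b, atol=1e-13, btol=1e-13, maxiter=5000)[0]
    out = v.ravel() - corr
    resid = np.linalg.norm(D @ out)
    # tolerance on the scale of the field's own divergence content
    scale = max(np.linalg.norm(b), np.linalg.norm(v) / max(min(spacings), 1e-30))
    if resid > 1e-8 * scale:
        raise RuntimeError(
            f"divergence projection did not converge (residual {resid:.3g} "
            f"vs scale {scale:.3g})")
    return out.reshape(v.shape)


def _project_spectral(v: np.ndarray,
                      spacings: tuple[float, float, float]) -> np.ndarray:
    """Transverse (Helmholtz) projection with even reflective padding."""
    nz, ny, nx = v.shape[:3]
    dz, dy, dx = spacings
    pad = [(0, nz - 2), (0, ny - 2), (0, nx - 2)]
    vp = np.stack([
        np.pad(v[..., c], pad, mode="reflect") for c in range(3)
    ], axis=-1)
    kz = 2.0 * np.pi * np.fft.fftfreq(vp.shape[0], d=dz)
    ky = 2.0 * np.pi * np.fft.fftfreq(vp.shape[1], d=dy)
    kx = 2.0 * np.pi * np.fft.fftfreq(vp.shape[2], d=dx)
    KZ, KY, KX = np.meshgrid(kz, ky, kx, indexing="ij")
    # discrete symbol of the centred two-point divergence, sin(k d)/d
    KZ = np.sin(KZ * dz) / dz
    KY = np.sin(KY * dy) / dy
    KX = np.sin(KX * dx) / dx
    k2 = KX**2 + KY**2 + KZ**2
    k2[k2 == 0] = 1.0  # mean and symbol-null (Nyquist) modes pass through
    vh = np.fft.fftn(vp, axes=(0, 1, 2))
    kdotv = KX * vh[..., 0] + KY * vh[..., 1] + KZ * vh[..., 2]
    for c, K in enumerate((KX, KY, KZ)):
        vh[..., c] -= K * kdotv / k2
    out = np.fft.ifftn(vh, axes=(0, 1, 2)).real
    return out[:nz, :ny, :nx]


def correct_stress(stress: StressTensorField, n_iter: int = 20,
                   backend: str = "exact") -> tuple[StressTensorField,
                                                    DivergenceReport]:
    """Iterative divergence correction of a symmetric stress field.

    Runs ``n_iter`` cycles of project-rows / reassemble / symmetrize and
    returns the corrected field together with the per-iteration interior
    divergence-norm trace (entry 0 is the uncorrected input).  Compatible
    symmetric inputs are fixed points.
    """
    g = stress.grid
    spacings = (g.dz, g.dy, g.dx)
    sigma = stress.sigma.copy()
    norms = [interior_divergence_norm(stress)]
    for _ in range(n_iter):
        w = np.empty_like(sigma)
        for i in range(3):
            w[..., i, :] = project_divergence_free(
                sigma[..., i, :], spacings, backend=backend)
        sigma = 0.5 * (w + np.swapaxes(w, -1, -2))
        norms.append(interior_divergence_norm(StressTensorField(g, sigma)))
    return (StressTensorField(g, sigma),
            DivergenceReport(norms=np.asarray(norms)))
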