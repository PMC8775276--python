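"""Fourier Transform Traction Cytometry with Tikhonov regularization.

The sampled displacement plane is expanded in the DFT plane-wave basis of
its grid; each wavenumber mode then decouples,

    u^_mn = G~(k_mn, h) . tau^_mn,

with the 2x2 tangential kernel (2D FTTC) or the full 3x3 kernel at depth h
(2.5D FTTC).  Because the kernel scales like 1/k the inversion is
ill-posed; 0th-order Tikhonov regularization replaces the naive inverse by

    tau^ = (G~+ G~ + lambda^2 I)^-1 G~+ u^,

and the regularization strength is chosen by generalized cross-validation:
lambda* minimises

    G(lambda) = || G~ tau^_lambda - u^ ||^2 / tr(1 - G~ G~#)^2

accumulated over all retained modes.  The k = 0 mode carries the net force,
which the half-space kernel cannot see (G~ is singular there); it is
dropped, so FTTC reconstructions always have zero force monopole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from .elasticity import ElasticMaterial, greens_fourier_2d, greens_fourier_25d
from .fields import DisplacementField, GridSpec, TractionField
from .results import ReconstructionResult

__all__ = [
    "FTTCOptions",
    "forward_fourier",
    "tikhonov_invert",
    "gcv_score",
    "select_lambda",
    "reconstruct_fttc",
    "interpolate_to_grid",
]


@dataclass(frozen=True)
class FTTCOptions:
    """Options for the Fourier-space inversion.

    mode
        "2.5d" (full 3x3 kernel, normal traction included) or "2d"
        (tangential 2x2 kernel; u_z is ignored).
    lambda_policy
        "gcv" for generalized cross-validation, or a fixed lambda >= 0
        (same units as the kernel's singular values, um/Pa).
    plane_depth
        Depth h of the displacement plane; None takes it from the grid.
    pad_factor
        Zero-padding factor for the *forward* model only; the inversion
        itself is the standard cyclic mode-by-mode solve.
    lambda_bracket, n_lambda
        Log-spaced GCV search bracket relative to the median singular
        value of the mode blocks, and the number of samples.
    """

    mode: str = "2.5d"
    lambda_policy: float | str = "gcv"
    plane_depth: float | None = None
    pad_factor: int = 1
    lambda_bracket: Tuple[float, float] = (1e-6, 1e2)
    n_lambda: int = 61

    def __post_init__(self) -> None:
        if self.mode not in ("2d", "2.5d"):
            raise ValueError("mode must be '2d' or '2.5d'")
        if not (self.lambda_policy == "gcv"
                or (np.isscalar(self.lambda_policy)
                    and float(self.lambda_policy) >= 0)):
            raise ValueError("lambda_policy must be 'gcv' or a number >= 0")


def _depth(u: DisplacementField, options: FTTCOptions) -> float:
    return (options.plane_depth if options.plane_depth is not None
            else u.grid.plane_depth)


def _hermitian_pairing(Gfull: np.ndarray) -> np.ndarray:
    """Project the mode-wise kernel onto real-operator consistency.

    A real-to-real cyclic convolution needs H(-k mod N) = conj(H(k)).  The
    continuous kernel satisfies this automatically except on the Nyquist
    lines of an even grid, where +k and -k alias onto the same index;
    averaging each block with the conjugate of its negated-index partner
    restores the pairing (and is the identity elsewhere).
    """
    rev = np.roll(np.flip(Gfull, axis=(0, 1)), shift=(1, 1), axis=(0, 1))
    return 0.5 * (Gfull + rev.conj())


def _kernel_on(KX: np.ndarray, KY: np.ndarray, h: float,
               material: ElasticMaterial,
               mode: str) -> tuple[np.ndarray, np.ndarray]:
    """(mask, blocks) of the real-operator-consistent kernel on a k-mesh."""
    mask = np.hypot(KX, KY) > 0
    dim = 2 if mode == "2d" else 3
    Gfull = np.zeros(KX.shape + (dim, dim), dtype=complex)
    if mode == "2d":
        Gfull[mask] = greens_fourier_2d(KX[mask], KY[mask], material)
    else:
        Gfull[mask] = greens_fourier_25d(KX[mask], KY[mask], h, material)
    Gfull = _hermitian_pairing(Gfull)
    return mask, Gfull[mask]


def _kernel(grid: GridSpec, h: float, material: ElasticMaterial,
            mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Kernel blocks for every retained (k != 0) mode of a grid.

    Returns (mask, G) with ``mask`` the (ny, nx) retained-mode mask and
    ``G`` of shape (n_modes, dim, dim).
    """
    KX, KY = grid.wavenumbers()
    return _kernel_on(KX, KY, h, material, mode)


def _components(mode: str) -> int:
    return 2 if mode == "2d" else 3


class _ModeSystem:
    """Per-mode SVD of the kernel applied to one displacement plane."""

    def __init__(self, u: DisplacementField, options: FTTCOptions,
                 material: ElasticMaterial):
        if u.grid.is_volume:
            raise ValueError("FTTC consumes a plane displacement field")
        self.grid = u.grid
        self.options = options
        dim = _components(options.mode)
        self.mask, self.G = _kernel(u.grid, _depth(u, options), material,
                                    options.mode)
        uh = np.fft.fft2(u.u[..., :dim], axes=(0, 1))
        self.uh = uh[self.mask]  # (M, dim)
        self.U, self.s, self.Vh = np.linalg.svd(self.G)
        self.beta = np.einsum("mji,mj->mi", self.U.conj(), self.uh)

    def gcv(self, lam: float) -> float:
        s2 = self.s**2
        filt = lam**2 / (s2 + lam**2)
        resid = np.sum(filt**2 * np.abs(self.beta) ** 2)
        trace = np.sum(filt)
        if trace == 0:
            raise ZeroDivisionError("GCV trace vanished (lambda = 0)")
        return float(resid / trace**2)


def forward_fourier(traction: TractionField, h: float,
                    material: ElasticMaterial, mode: str = "2.5d",
                    pad_factor: int = 1) -> DisplacementField:
    """Displacement plane at depth h induced by a sampled traction field.

    Mode-by-mode product of the DFT of the sampled traction with the
    Fourier-space kernel.  ``pad_factor`` > 1 zero-pads the traction first,
    which approximates the infinite-plane (acyclic) convolution for
    compactly supported traction; the zero mode is dropped either way.
    """
    grid = traction.grid
    npx, npy = pad_factor * grid.nx, pad_factor * grid.ny
    dim = _components(mode)
    tpad = np.zeros((npy, npx, dim))
    tpad[: grid.ny, : grid.nx] = traction.t[..., :dim]
    th = np.fft.fft2(tpad, axes=(0, 1))
    kx = 2.0 * np.pi * np.fft.fftfreq(npx, d=grid.dx)
    ky = 2.0 * np.pi * np.fft.fftfreq(npy, d=grid.dy)
    KX, KY = np.meshgrid(kx, ky, indexing="xy")
    mask, G = _kernel_on(KX, KY, h, material, mode)
    uh = np.zeros_like(th, dtype=complex)
    uh[mask] = np.einsum("mij,mj->mi", G, th[mask])
    u = np.fft.ifft2(uh, axes=(0, 1)).real[: grid.ny, : grid.nx]
    if dim == 2:
        u = np.concatenate([u, np.zeros(u.shape[:2] + (1,))], axis=-1)
    out_grid = replace(grid, plane_depth=h)
    return DisplacementField(out_grid, u)


def _invert_modes(G: np.ndarray, uh: np.ndarray, lam: float) -> np.ndarray:
    """Per-mode Tikhonov solve tau^ = (G+G + lam^2 I)^-1 G+ u^."""
    dim = G.shape[-1]
    Gh = np.swapaxes(G.conj(), -1, -2)
    A = Gh @ G + lam**2 * np.eye(dim)
    rhs = np.einsum("mij,mj->mi", Gh, uh)
    return np.linalg.solve(A, rhs[..., None])[..., 0]


def tikhonov_invert(u: DisplacementField, lam: float, options: FTTCOptions,
                    material: ElasticMaterial) -> TractionField:
    """Invert one displacement plane at fixed regularization strength.

    lam = 0 performs the plain (unregularized) mode-by-mode inverse; an
    ill-conditioning warning carrying the worst mode condition number is
    issued, since noise will then be amplified by that factor.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if u.grid.is_volume:
        raise ValueError("FTTC consumes a plane displacement field")
    grid = u.grid
    dim = _components(options.mode)
    mask, G = _kernel(grid, _depth(u, options), material, options.mode)
    uh = np.fft.fft2(u.u[..., :dim], axes=(0, 1))
    if lam == 0:
        s = np.linalg.svd(G, compute_uv=False)
        cond = float(s.max() / s.min())  # whole block-diagonal operator
        if cond > 1e6:
            warnings.warn(
                f"unregularized inversion is ill-conditioned (worst mode "
                f"condition number {cond:.3g}); noise will be amplified",
                stacklevel=2,
            )
    th = np.zeros_like(uh, dtype=complex)
    th[mask] = _invert_modes(G, uh[mask], lam)
    t = np.fft.ifft2(th, axes=(0, 1)).real
    if dim == 2:
        t = np.concatenate([t, np.zeros(t.shape[:2] + (1,))], axis=-1)
    return TractionField(grid.surface() if grid.is_volume else
                         replace(grid, plane_depth=0.0), t)


def gcv_score(lam: float, u: DisplacementField, options: FTTCOptions,
              material: ElasticMaterial, method: str = "svd") -> float:
    """Generalized cross-validation score G(lambda) over all retained modes.

    method="svd" uses the singular values of each mode block;
    method="explicit" forms the regularized solution and residual with
    dense per-mode matrix algebra (independent route, used for checking).
    """
    if lam <= 0:
        raise ValueError("GCV is evaluated for lambda > 0")
    system = _ModeSystem(u, options, material)
    if method == "svd":
        return system.gcv(lam)
    if method != "explicit":
        raise ValueError("method must be 'svd' or 'explicit'")
    G, uh = system.G, system.uh
    dim = G.shape[-1]
    th = _invert_modes(G, uh, lam)
    resid = np.sum(np.abs(np.einsum("mij,mj->mi", G, th) - uh) ** 2)
    Gh = np.swapaxes(G.conj(), -1, -2)
    A = Gh @ G + lam**2 * np.eye(dim)
    GGsharp = G @ np.linalg.solve(A, Gh)
    trace = np.sum(np.trace(np.eye(dim) - GGsharp, axis1=-2, axis2=-1)).real
    return float(resid / trace**2)


def select_lambda(u: DisplacementField, options: FTTCOptions,
                  material: ElasticMaterial) -> tuple[float, np.ndarray]:
    """GCV choice of lambda: log-spaced bracket scan plus local refinement.

    The bracket is ``options.lambda_bracket`` times the median singular
    value of the mode blocks.  If the coarse minimum sits on a bracket
    edge the bracket is extended once (with a warning).  Returns
    (lambda*, curve) with ``curve`` the sampled (lambda, G(lambda)) pairs.
    """
    system = _ModeSystem(u, options, material)
    s_med = float(np.median(system.s))
    lo, hi = (b * s_med for b in options.lambda_bracket)
    lams = np.geomspace(lo, hi, options.n_lambda)
    scores = np.array([system.gcv(l) for l in lams])
    i = int(np.argmin(scores))
    if i in (0, len(lams) - 1):
        warnings.warn(
            "GCV minimum at the bracket edge; extending the bracket once",
            stacklevel=2,
        )
        if i == 0:
            lams = np.geomspace(lo * 1e-4, hi, options.n_lambda + 20)
        else:
            lams = np.geomspace(lo, hi * 1e4, options.n_lambda + 20)
        scores = np.array([system.gcv(l) for l in lams])
        i = int(np.argmin(scores))
    lo_ref = lams[max(i - 1, 0)]
    hi_ref = lams[min(i + 1, len(lams) - 1)]
    res = minimize_scalar(
        lambda x: system.gcv(float(np.exp(x))),
        bounds=(np.log(lo_ref), np.log(hi_ref)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    lam_star = float(np.exp(res.x))
    curve = np.column_stack([lams, scores])
    return lam_star, curve


def reconstruct_fttc(u: DisplacementField, options: FTTCOptions,
                     material: ElasticMaterial) -> ReconstructionResult:
    """Full FTTC pipeline on a gridded displacement plane.

    Applies the lambda policy (fixed value or GCV), performs the
    mode-by-mode Tikhonov inversion, and returns the traction with
    diagnostics (Fourier-domain residual and solution norms, lambda).
    """
    if u.grid.is_volume:
        u = u.surface_layer()
    curve = None
    if options.lambda_policy == "gcv":
        lam, curve = select_lambda(u, options, material)
    else:
        lam = float(options.lambda_policy)
    traction = tikhonov_invert(u, lam, options, material)
    # Fourier-domain diagnostics
    dim = _components(options.mode)
    mask, G = _kernel(u.grid, _depth(u, options), material, options.mode)
    uh = np.fft.fft2(u.u[..., :dim], axes=(0, 1))[mask]
    th = np.fft.fft2(traction.t[..., :dim], axes=(0, 1))[mask]
    resid = float(np.linalg.norm(np.einsum("mij,mj->mi", G, th) - uh))
    return ReconstructionResult(
        traction=traction,
        lambda_used=lam,
        gcv_curve=curve,
        diagnostics={
            "residual_norm": resid,
            "solution_norm": float(np.linalg.norm(th)),
            "n_modes": int(mask.sum()),
        },
    )


def interpolate_to_grid(points: np.ndarray, values: np.ndarray,
                        grid: GridSpec) -> DisplacementField:
    """Piecewise-linear interpolation of scattered displacement data onto a
    regular plane grid (triangulation-based); nodes outside the convex hull
    are zero-filled with a warning."""
    from scipy.interpolate import LinearNDInterpolator

    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    interp = LinearNDInterpolator(points[:, :2], values)
    X, Y = grid.xy_mesh()
    u = interp(np.column_stack([X.ravel(), Y.ravel()]))
    u = u.reshape(grid.ny, grid.nx, values.shape[1])
    bad = ~np.isfinite(u)
    if bad.any():
        warnings.warn(
            f"{int(bad.any(axis=-1).sum())} grid nodes outside the data hull "
            "were zero-filled", stacklevel=2)
        u[bad] = 0.0
    return DisplacementField(grid, u)
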