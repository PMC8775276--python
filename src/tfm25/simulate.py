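"""Synthetic traction patterns and their exact substrate displacements.

Ground-truth tractions are superpositions of Hertz-like circular patches

    tau(x, y) = 3 Q / (2 pi a^3) * sqrt(a^2 - rho^2)   for rho <= a,

where ``Q`` is the total transmitted force (the profile integrates to ``Q``
exactly), ``a`` the patch radius and ``rho`` the distance to the patch
centre.  This is the pressure profile of the Hertz and Cerruti contact
problems, so a purely normal single patch is a rigid-sphere indenter.

Displacements follow from the Boussinesq convolution.  Two evaluation
routes are provided: a fast Fourier route that multiplies the analytic
patch transform with the closed-form Fourier-space Green's function on a
zero-padded wavenumber grid (with an analytic treatment of the
near-zero-wavenumber cells, where the 1/k singularity makes plain midpoint
sampling inaccurate), and a slow real-space quadrature route that
integrates the convolution directly and serves as an independent
reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss

from .elasticity import ElasticMaterial, greens_fourier_25d, greens_real
from .fields import PN_PER_UN, DisplacementField, GridSpec, TractionField

__all__ = [
    "HertzPatch",
    "TractionPattern",
    "NoiseSpec",
    "patch_traction",
    "patch_traction_fourier",
    "displacement_from_pattern",
    "displacement_at_points_quadrature",
    "add_noise",
    "preset_pattern",
    "PRESET_NAMES",
    "centered_volume_grid",
    "centered_surface_grid",
]


@dataclass(frozen=True)
class HertzPatch:
    """One circular Hertz-like traction patch.

    ``load`` is the total transmitted force vector in pN (= Pa um^2); the
    sqrt profile is normalised so that the patch traction integrates to
    exactly this vector.
    """

    center: tuple[float, float]
    radius: float
    load: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("patch radius must be positive")

    @property
    def load_vector(self) -> np.ndarray:
        return np.asarray(self.load, dtype=float)

    @property
    def peak_traction(self) -> float:
        """|tau| at the patch centre: 3 |Q| / (2 pi a^2), in Pa."""
        return 3.0 * float(np.linalg.norm(self.load_vector)) / (
            2.0 * np.pi * self.radius**2)


@dataclass
class TractionPattern:
    """An ordered superposition of Hertz-like patches (may be empty)."""

    patches: list[HertzPatch] = field(default_factory=list)
    name: str = ""

    def total_load(self) -> np.ndarray:
        """Sum of patch forces (the pattern's force monopole), pN."""
        if not self.patches:
            return np.zeros(3)
        return np.sum([p.load_vector for p in self.patches], axis=0)


@dataclass(frozen=True)
class NoiseSpec:
    """Gaussian displacement noise, scaled to the field's mean amplitude.

    ``sigma_rel`` is sigma_N / <||u||>: the per-component standard deviation
    of the added i.i.d. Gaussian noise divided by the mean
    displacement-vector magnitude of the clean field.
    """

    sigma_rel: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_rel < 0:
            raise ValueError("sigma_rel must be >= 0")


def patch_traction(pattern: TractionPattern, grid: GridSpec) -> TractionField:
    """Sample the exact pattern traction on a surface grid."""
    if grid.is_volume:
        raise ValueError("traction is sampled on a surface grid")
    X, Y = grid.xy_mesh()
    t = np.zeros((grid.ny, grid.nx, 3))
    for p in pattern.patches:
        rho2 = (X - p.center[0]) ** 2 + (Y - p.center[1]) ** 2
        supp = rho2 < p.radius**2
        prof = np.zeros_like(rho2)
        prof[supp] = np.sqrt(p.radius**2 - rho2[supp])
        amp = 3.0 / (2.0 * np.pi * p.radius**3)
        t += amp * prof[..., None] * p.load_vector
    return TractionField(grid, t)


def _sphere_form_factor(x: np.ndarray) -> np.ndarray:
    """f(x) = 3 (sin x - x cos x) / x^3 with f(0) = 1, numerically stable."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-3
    xs = x[small]
    out[small] = 1.0 - xs**2 / 10.0 + xs**4 / 280.0
    xl = x[~small]
    out[~small] = 3.0 * (np.sin(xl) - xl * np.cos(xl)) / xl**3
    return out


def patch_traction_fourier(patch: HertzPatch, kx, ky) -> np.ndarray:
    """Continuous 2D Fourier transform of one patch's traction, (..., 3).

    tau~(k) = 3 Q (sin(k a) - k a cos(k a)) / (a^3 k^3) * e^{-i k . x0};
    the k -> 0 limit equals Q (the zero mode is the total load).  Units
    pN (= Pa um^2, traction times area).
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    k = np.hypot(kx, ky)
    form = _sphere_form_factor(k * patch.radius)
    phase = np.exp(-1j * (kx * patch.center[0] + ky * patch.center[1]))
    return (form * phase)[..., None] * patch.load_vector


def _pattern_fourier(pattern: TractionPattern, kx, ky,
                     origin: tuple[float, float]) -> np.ndarray:
    """Pattern transform with centres taken relative to ``origin``."""
    out = np.zeros(np.broadcast(np.asarray(kx), np.asarray(ky)).shape + (3,),
                   dtype=complex)
    for p in pattern.patches:
        shifted = HertzPatch(
            center=(p.center[0] - origin[0], p.center[1] - origin[1]),
            radius=p.radius, load=p.load)
        out += patch_traction_fourier(shifted, kx, ky)
    return out


def displacement_from_pattern(
    pattern: TractionPattern,
    grid: GridSpec,
    material: ElasticMaterial,
    method: str = "fourier",
    pad_factor: int = 4,
    split_scale: float = 4.0,
) -> DisplacementField:
    """Evaluate the exact displacement of a pattern on a plane or volume grid.

    method="fourier"
        Per z-layer, multiply the analytic pattern transform with the
        2.5D Fourier-space Green's function and inverse-transform.  The
        kernel is split Ewald-style at the wavenumber scale
        ``sigma_k = split_scale * 2 pi / L_pad``: the long-wavelength part
        ``G~ exp(-k^2/2 sigma_k^2)``, which carries the 1/k singularity,
        is integrated directly in polar wavenumber coordinates (it is
        smooth on the scale of the field of view, so it is evaluated on a
        coarse mesh and splined); the complementary short part is regular
        at k = 0 and its real-space kernel is localized, so evaluating it
        with an FFT on a grid zero-padded by ``pad_factor`` leaves only a
        negligible periodic wrap-around.  Together the two parts
        reproduce the infinite-plane convolution.
    method="quadrature"
        Direct real-space integration of the Boussinesq convolution per
        node (slow; reference implementation).
    """
    if method == "quadrature":
        X, Y = grid.xy_mesh()
        zs = grid.z
        pts = np.stack([
            np.broadcast_to(X, (len(zs),) + X.shape).ravel(),
            np.broadcast_to(Y, (len(zs),) + Y.shape).ravel(),
            np.repeat(zs, X.size),
        ], axis=-1)
        u = displacement_at_points_quadrature(pattern, pts, material)
        u = u.reshape((len(zs), grid.ny, grid.nx, 3))
        if not grid.is_volume:
            u = u[0]
        return DisplacementField(grid, u)
    if method != "fourier":
        raise ValueError(f"unknown method {method!r}")
    if pad_factor < 1:
        raise ValueError("pad_factor must be >= 1")

    from scipy.interpolate import RectBivariateSpline

    npx, npy = pad_factor * grid.nx, pad_factor * grid.ny
    kx1 = 2.0 * np.pi * np.fft.fftfreq(npx, d=grid.dx)
    ky1 = 2.0 * np.pi * np.fft.fftfreq(npy, d=grid.dy)
    KX, KY = np.meshgrid(kx1, ky1, indexing="xy")
    K = np.hypot(KX, KY)
    kmask = K > 0
    origin = (grid.origin[0], grid.origin[1])
    tau_hat = _pattern_fourier(pattern, KX[kmask], KY[kmask], origin)
    sigma_k = split_scale * 2.0 * np.pi / max(npx * grid.dx, npy * grid.dy)
    short_weight = -np.expm1(-K[kmask] ** 2 / (2.0 * sigma_k**2))

    # polar quadrature for the long-wavelength (singular) part
    k_cut = 6.0 * sigma_k
    n_r, n_phi = 48, 64
    xg, wg = leggauss(n_r)
    kr = 0.5 * k_cut * (xg + 1.0)
    wr = 0.5 * k_cut * wg
    phis = (np.arange(n_phi) + 0.5) * (2.0 * np.pi / n_phi)
    QK = kr[:, None] * np.cos(phis)[None, :]
    QL = kr[:, None] * np.sin(phis)[None, :]
    qkx, qky = QK.ravel(), QL.ravel()
    qw = (wr[:, None] * kr[:, None] * (2.0 * np.pi / n_phi)
          * np.exp(-kr[:, None] ** 2 / (2.0 * sigma_k**2))
          * np.ones((1, n_phi))).ravel()
    qtau = _pattern_fourier(pattern, qkx, qky, origin)

    # coarse in-plane mesh for the smooth long part (relative coordinates)
    lam_min = 2.0 * np.pi / k_cut
    step = lam_min / 6.0
    xr_max = grid.dx * (grid.nx - 1)
    yr_max = grid.dy * (grid.ny - 1)
    xc = np.linspace(0.0, xr_max, max(int(np.ceil(xr_max / step)) + 1, 8))
    yc = np.linspace(0.0, yr_max, max(int(np.ceil(yr_max / step)) + 1, 8))
    XC, YC = np.meshgrid(xc, yc, indexing="xy")
    qphase = np.exp(1j * (qkx[:, None, None] * XC + qky[:, None, None] * YC))
    xr = grid.dx * np.arange(grid.nx)
    yr = grid.dy * np.arange(grid.ny)

    zs = grid.z
    layers = np.empty((len(zs), grid.ny, grid.nx, 3))
    for li, z in enumerate(zs):
        # short part: FFT on the padded grid
        G = greens_fourier_25d(KX[kmask], KY[kmask], z, material)
        u_hat = np.zeros((npy, npx, 3), dtype=complex)
        u_hat[kmask] = np.einsum(
            "gij,gj->gi", G, tau_hat) * short_weight[:, None]
        u_pad = np.fft.ifft2(u_hat, axes=(0, 1)).real / (grid.dx * grid.dy)
        u = u_pad[: grid.ny, : grid.nx].copy()
        # long part: polar quadrature on the coarse mesh, then spline
        Gq = greens_fourier_25d(qkx, qky, z, material)
        fq = np.einsum("gij,gj->gi", Gq, qtau) * qw[:, None]
        coarse = np.einsum("gyx,gi->yxi", qphase, fq).real / (4.0 * np.pi**2)
        for c in range(3):
            spl = RectBivariateSpline(yc, xc, coarse[..., c], kx=3, ky=3)
            u[..., c] += spl(yr, xr)
        layers[li] = u
    if grid.is_volume:
        return DisplacementField(grid, layers)
    return DisplacementField(grid, layers[0])


def displacement_at_points_quadrature(
    pattern: TractionPattern,
    points: np.ndarray,
    material: ElasticMaterial,
    n_phi: int = 128,
    n_t: int = 16,
) -> np.ndarray:
    """Displacement at arbitrary points by real-space convolution quadrature.

    For each point and patch the convolution is taken in line coordinates
    through the evaluation point: for every direction the patch disk is
    crossed on a chord [s-, s+] along which the Hertz profile equals
    (3/2 pi a^3) sqrt((s+ - s)(s - s-)), so the substitution
    s = p + h sin t removes the square-root edge cusp exactly, and the
    polar Jacobian |s| cancels the 1/r surface singularity of the
    Boussinesq kernel.  Slow but accurate; used as the reference oracle
    for the Fourier route.

    ``points`` is (N, 3) with columns x, y, z (um); returns (N, 3) in um.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.zeros((len(points), 3))
    tg, tw = leggauss(n_t)
    for pi, (px, py, pz) in enumerate(points):
        u = np.zeros(3)
        for patch in pattern.patches:
            dx = patch.center[0] - px
            dy = patch.center[1] - py
            d2 = dx * dx + dy * dy
            amp = 3.0 / (2.0 * np.pi * patch.radius**3)
            if d2 > patch.radius**2:
                # exterior point: only directions through the disk matter
                half = math.asin(patch.radius / math.sqrt(d2))
                phi_c = math.atan2(dy, dx)
                dphi = 2.0 * half / n_phi
                phis = phi_c - half + (np.arange(n_phi) + 0.5) * dphi
            else:
                dphi = np.pi / n_phi
                phis = (np.arange(n_phi) + 0.5) * dphi
            s_list, phi_list, w_list = [], [], []
            for phi in phis:
                c, s_ = math.cos(phi), math.sin(phi)
                p = c * dx + s_ * dy
                disc = p * p - (d2 - patch.radius**2)
                if disc <= 0:
                    continue
                h = math.sqrt(disc)
                s_lo, s_hi = p - h, p + h
                # split the chord at s = 0 where the integrand direction flips
                if s_lo < 0.0 < s_hi:
                    t_split = math.asin(max(-1.0, min(1.0, -p / h)))
                    pieces = [(-0.5 * np.pi, t_split), (t_split, 0.5 * np.pi)]
                else:
                    pieces = [(-0.5 * np.pi, 0.5 * np.pi)]
                for ta, tb in pieces:
                    tm = 0.5 * (ta + tb)
                    th = 0.5 * (tb - ta)
                    t = tm + th * tg
                    sv = p + h * np.sin(t)
                    wv = (amp * (h * np.cos(t)) ** 2 * np.abs(sv)
                          * th * tw * dphi)
                    s_list.append(sv)
                    phi_list.append(np.full_like(sv, phi))
                    w_list.append(wv)
            if not s_list:
                continue
            sv = np.concatenate(s_list)
            phv = np.concatenate(phi_list)
            wv = np.concatenate(w_list)
            sv = np.where(sv == 0.0, 1e-12, sv)
            gx = sv * np.cos(phv)
            gy = sv * np.sin(phv)
            G = greens_real(-gx, -gy, pz, material)
            u += np.einsum("g,gij,j->i", wv, G, patch.load_vector)
        out[pi] = u
    return out


def add_noise(fieldv: DisplacementField, noise: NoiseSpec) -> DisplacementField:
    """Perturb every Cartesian displacement component with i.i.d. Gaussian
    noise of standard deviation ``sigma_rel * <||u||>``.

    The normalisation <||u||> is the mean displacement-vector magnitude of
    the input field, so ``sigma_rel`` is directly the noise level quoted
    for the simulation protocol.  Deterministic given ``noise.seed``.
    """
    if noise.sigma_rel == 0:
        return DisplacementField(fieldv.grid, fieldv.u.copy())
    umean = fieldv.mean_magnitude()
    if umean == 0:
        raise ValueError(
            "cannot scale noise to a zero displacement field "
            "(<||u||> = 0 leaves sigma undefined)"
        )
    rng = np.random.default_rng(noise.seed)
    pert = rng.normal(0.0, noise.sigma_rel * umean, size=fieldv.u.shape)
    return DisplacementField(fieldv.grid, fieldv.u + pert)


def _balanced(loads: np.ndarray) -> np.ndarray:
    """Remove the floating-point residual so the loads sum to exactly zero."""
    return loads - loads.mean(axis=0, keepdims=True)


def _ring_positions(n: int, radius: float, phase: float = 0.0) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.stack([radius * np.cos(ang), radius * np.sin(ang)], axis=-1)


PRESET_NAMES = ("indenter", "ring_dipole", "cell_like", "adhesion_array")


def preset_pattern(name: str, **overrides) -> TractionPattern:
    """Named test patterns.

    indenter
        One purely normal patch (spherical indenter pushing into the
        substrate) with total F_z = 10 uN; a force monopole.
    ring_dipole
        A ring of patches with alternating-sign normal loads; F_z = 0.
    cell_like
        A broad central normal push (the nucleus) balanced by peripheral
        patches that pull up and point tangentially inward (focal
        adhesions); the total force vanishes in all three components.
    adhesion_array
        A ring of circular adhesion sites with purely tangential,
        inward-pointing (contractile) loads summing to zero.

    Geometry and loads are configurable through keyword overrides
    (``radius``, ``patch_radius``, ``ring_radius``, ``n_patches``,
    ``total_fz_un``, ``load_un``, ``center`` as applicable).
    """
    if name == "indenter":
        a = overrides.pop("radius", 5.0)
        fz = overrides.pop("total_fz_un", 10.0) * PN_PER_UN
        cx, cy = overrides.pop("center", (0.0, 0.0))
        _check_no_overrides(name, overrides)
        return TractionPattern(
            [HertzPatch((cx, cy), a, (0.0, 0.0, fz))], name=name)

    if name == "ring_dipole":
        n = overrides.pop("n_patches", 8)
        if n % 2:
            raise ValueError("ring_dipole needs an even patch count")
        a = overrides.pop("patch_radius", 2.0)
        R = overrides.pop("ring_radius", 7.0)
        per = overrides.pop("single_sign_fz_un", 10.0) / (n // 2) * PN_PER_UN
        _check_no_overrides(name, overrides)
        pos = _ring_positions(n, R)
        patches = [
            HertzPatch(tuple(pos[i]), a,
                       (0.0, 0.0, per if i % 2 == 0 else -per))
            for i in range(n)
        ]
        return TractionPattern(patches, name=name)

    if name == "cell_like":
        n = overrides.pop("n_patches", 8)
        a_c = overrides.pop("nucleus_radius", 5.0)
        a_p = overrides.pop("patch_radius", 1.6)
        R = overrides.pop("ring_radius", 9.0)
        fz = overrides.pop("nucleus_fz_un", 4.0) * PN_PER_UN
        ft = overrides.pop("adhesion_ft_un", 0.5) * PN_PER_UN
        _check_no_overrides(name, overrides)
        pos = _ring_positions(n, R)
        inward = -pos / np.linalg.norm(pos, axis=1, keepdims=True)
        loads = np.concatenate(
            [ft * inward, np.full((n, 1), -fz / n)], axis=1)
        loads = np.vstack([loads, [0.0, 0.0, fz]])
        loads = _balanced(loads)
        patches = [HertzPatch(tuple(pos[i]), a_p, tuple(loads[i]))
                   for i in range(n)]
        patches.append(HertzPatch((0.0, 0.0), a_c, tuple(loads[n])))
        return TractionPattern(patches, name=name)

    if name == "adhesion_array":
        n = overrides.pop("n_patches", 8)
        a = overrides.pop("patch_radius", 2.0)
        R = overrides.pop("ring_radius", 8.0)
        ft = overrides.pop("adhesion_ft_un", 0.4) * PN_PER_UN
        _check_no_overrides(name, overrides)
        pos = _ring_positions(n, R)
        inward = -pos / np.linalg.norm(pos, axis=1, keepdims=True)
        loads = _balanced(np.concatenate(
            [ft * inward, np.zeros((n, 1))], axis=1))
        patches = [HertzPatch(tuple(pos[i]), a, tuple(loads[i]))
                   for i in range(n)]
        return TractionPattern(patches, name=name)

    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def _check_no_overrides(name: str, leftovers: dict) -> None:
    if leftovers:
        raise TypeError(
            f"unknown overrides for preset {name!r}: {sorted(leftovers)}")


def centered_volume_grid(nx: int = 64, ny: int = 64, nz: int = 9,
                         dx: float = 0.4, dz: float | None = None) -> GridSpec:
    """A volume grid centred on the origin, starting at the z = 0 surface.

    Defaults follow the simulation protocol: 0.4 um in-plane spacing and a
    coarser z spacing (dz = 2 dx) mimicking anisotropic confocal sampling.
    """
    if dz is None:
        dz = 2.0 * dx
    return GridSpec(nx=nx, ny=ny, dx=dx, dy=dx, nz=nz, dz=dz,
                    origin=(-dx * (nx - 1) / 2.0, -dx * (ny - 1) / 2.0, 0.0))


def centered_surface_grid(nx: int = 64, ny: int = 64, dx: float = 0.4,
                          plane_depth: float = 0.0) -> GridSpec:
    """A surface plane grid centred on the origin."""
    return GridSpec(nx=nx, ny=ny, dx=dx, dy=dx,
                    origin=(-dx * (nx - 1) / 2.0, -dx * (ny - 1) / 2.0, 0.0),
                    plane_depth=plane_depth)
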