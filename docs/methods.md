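# Methods

## Physical model

The substrate is a homogeneous, isotropic, linearly elastic half-space
occupying `z > 0`, with Young's modulus `E` and Poisson ratio `ν`.  The free
surface is the plane `z = 0` with outward normal along `−z`, so the surface
traction exerted by the cell is read off the Cauchy stress as
`τ = −(σ₁₃, σ₂₃, σ₃₃)|_{z=0}`.  Small deformations are assumed throughout:
the Lagrange/Euler distinction is neglected and stress follows Hooke's law

    σ = μ (∇u + ∇uᵀ) + [2μν/(1−2ν)] (∇·u) I,       μ = E / 2(1+ν).

Units are µm for length, Pa for stress; traction integrated over area is
therefore in Pa·µm² = pN, converted to µN only at the I/O boundary.
Defaults are `E = 10 kPa` and `ν = 0.49` (a typical nearly incompressible
polyacrylamide substrate); `ν = 0.5` exactly is rejected wherever the
dilatational modulus `2μν/(1−2ν)` appears.

Traction and displacement are linked by the Boussinesq–Cerruti convolution
`u = G * τ`.  The package carries three forms of the kernel:

* `greens_real(x, y, z)` — the classical point-force solution on the
  half-space (degree −1 homogeneous, singular at the load point),
* `greens_fourier_2d(kx, ky)` — the tangential 2×2 surface kernel
  `[(1−ν)k² + ν k_y², −ν k_x k_y; ·, (1−ν)k² + ν k_x²] / (μk³)` used by 2D
  FTTC,
* `greens_fourier_25d(kx, ky, z)` — the full 3×3 kernel at depth `z`, with
  `e^{−kz}` envelope and imaginary tangential–normal coupling; its `z = 0`
  tangential block reduces exactly to the 2D kernel and the matrix is
  Hermitian at the surface.

The three are mutually validated in the test suite: an independent literal
transcription of the Cerruti/Boussinesq component formulas, and a numerical
2D Fourier transform of the real-space kernel that must agree with the
closed form within 1% on random `(k, z, ν)` probes.

## Forward simulation

Ground-truth tractions are superpositions of Hertz-like circular patches
`τ = (3Q/2πa³) √(a²−ρ²)` on `ρ ≤ a`, which integrate exactly to the load
`Q` and have the closed-form transform
`τ̃(k) = 3Q (sin ka − ka cos ka)/(a³k³) · e^{−i k·x₀}`.

Exact displacements are evaluated in Fourier space as `ũ = G̃(k, z) τ̃(k)`.
Because the kernel carries an integrable `1/k` singularity, plain sampling
of the product on a DFT grid computes a *periodic* field whose slowly
decaying image tails and missing zero mode leave an `O(a/L)` offset.  The
evaluator therefore splits the kernel Ewald-style at
`σ_k = 4·2π/L_pad`:

* the long-wavelength part `G̃ e^{−k²/2σ_k²}` (which carries the
  singularity) is integrated directly in polar wavenumber coordinates
  (48-point Gauss radially to `6σ_k`, 64 angles) — it is smooth on the
  field-of-view scale, so it is evaluated on a coarse in-plane mesh
  (≥ 6 samples per shortest wavelength) and cubic-splined;
* the complement is regular at `k = 0` and its real-space kernel is
  localized on the scale `1/σ_k`, so a zero-padded FFT (pad factor 4 by
  default) evaluates it with negligible wrap-around.

The slow reference route integrates the real-space convolution per point in
line coordinates through the evaluation point: along each chord the Hertz
profile factors as `√((s₊−s)(s−s₋))`, so the substitution `s = p + h sin t`
removes the edge cusp exactly while the polar Jacobian cancels the kernel's
`1/r` surface singularity; for exterior points the angular quadrature is
restricted to the patch's subtended window.  Fourier and quadrature routes
agree within 1% on every probe tested (typically a few 10⁻³).

Four presets define the study patterns: `indenter` (one purely normal
patch, total `F_z = 10 µN`, radius 5 µm), `ring_dipole` (8 patches,
ring radius 7 µm, a = 2 µm, alternating ±2.5 µN normal loads, net zero),
`cell_like` (a broad central normal push of 4 µN balanced by 8 peripheral
patches that pull up and point tangentially inward — nucleus plus focal
adhesions; all three force components sum to zero exactly), and
`adhesion_array` (8 purely tangential, inward-pointing 0.4 µN patches on an
8 µm ring).  The geometric parameters are package choices made for
qualitative fidelity to contractile cells on flat substrates and are all
configurable; the properties the tests rely on are only those the patterns
guarantee by construction (total loads and force balance).

The default sampling lattice is 64×64×9 nodes at 0.4 µm in-plane spacing
with `dz = 2 dx`, mimicking the anisotropic axial resolution of confocal
stacks.  Noise emulates displacement measurement error: i.i.d. Gaussian
perturbations of every Cartesian component with standard deviation
`σ_N = sigma_rel · ⟨‖u‖⟩`, where `⟨‖u‖⟩` is the mean displacement-vector
magnitude of the clean field being perturbed.  The generator does **not**
emulate bead rendering, point-spread functions, or tracking artifacts —
passing tests therefore demonstrate the mathematical behaviour of the
reconstructions under idealized Gaussian displacement noise, not their
robustness to image-processing error sources.

## Inverse route (FTTC)

The displacement plane is expanded in the DFT basis of its grid; each mode
decouples, `û_mn = G̃(k_mn, h) τ̂_mn`, with `h` the observation depth
(0 by default).  Tikhonov regularization solves
`τ̂ = (G̃†G̃ + λ²I)⁻¹ G̃† û` per mode; `mode="2d"` uses only the tangential
displacements and the 2×2 kernel, `mode="2.5d"` the full 3×3.

Numerical choices:

* **Zero mode.**  `G̃ ∝ 1/k` is singular at `k = 0`; the traction zero mode
  is set to zero, i.e. FTTC reconstructs zero net force.  (The direct
  method has no such restriction — it recovers monopoles.)
* **Nyquist pairing.**  On even grids the `+k`/`−k` Nyquist lines alias
  onto one index, where the continuous kernel violates the conjugate
  pairing `H(−k) = conj(H(k))` a real-to-real operator requires.  Each
  block is averaged with the conjugate of its negated-index partner
  (identity everywhere else).  Without this projection the real-valued
  inverse is not the per-mode minimizer and the Tikhonov residual is not
  monotone in λ.
* **GCV.**  `G(λ) = ‖G̃τ̂_λ − û‖² / tr(1 − G̃G̃#)²`, numerator and trace
  accumulated over all retained modes of the block-diagonal operator (the
  dropped zero mode is excluded from the trace; this shifts the
  denominator by a λ-independent count only).  The score is evaluated from
  the per-mode SVD; an independent dense-algebra route is kept for
  checking.  λ* is located on 61 log-spaced samples spanning
  `10⁻⁶–10²` × the median singular value, extended once if the minimum
  lands on an edge, then refined by bounded scalar minimization in log λ.
  On the synthetic benchmarks the GCV choice lands near the λ that
  minimizes the true reconstruction error.
* **Forward padding.**  `forward_fourier` optionally zero-pads (the
  inversion itself is the standard cyclic solve).  No window/taper is
  applied by default.
* Scattered input can be interpolated to the grid with triangulation-based
  linear interpolation; the synthetic pipelines bypass this step.

## Direct route

The displacement volume is differentiated per axis by one of three
schemes — centred two-point, five-node fourth-order, or an equal-weight
OLS linear fit over the 3×3×3 neighbourhood (the default).  The 3×3×3
slope reduces to a centred difference averaged over the 3×3 perpendicular
window, giving white-noise gradient standard deviations of
`σ/(√2 Δ)`, `√130/12 · σ/Δ` and `σ/(√18 Δ)` respectively — the fit is the
least noisy, the four-point stencil the noisiest.  Boundary handling:
one-sided two-point differences; one-sided five-node stencils of matching
order; and a support cube shifted to lie fully in-domain (which leaves the
boundary slope equal to the adjacent interior one).  These one-sided
boundary forms are what biases the surface normal force slightly — the
reconstructed indenter monopole comes out within ~1% of 10 µN on the
default grid.  Stress follows from Hooke's law; traction is read off the
`z = 0` layer without extrapolation.  The whole pipeline (without the
divergence correction) is linear in the input field, which makes the
seed-averaged `d_L2` an almost exact straight line in the noise level.

## Divergence correction

Static force balance requires `∂_j σ_ij = 0`; with noiseless data the
computed stress satisfies it, so any divergence measures noise.  The
correction iterates 20 fixed cycles of: split σ into row vector fields →
replace each by its nearest divergence-free field → reassemble →
symmetrize.  The projection minimizes the node-wise change subject to the
centred-difference divergence vanishing at all interior nodes (boundary
nodes carry no constraint) and is solved exactly through a cached sparse
factorization of the constraint normal matrix; the projection residual is
checked on every call.  Symmetrization partially restores divergence, so
the loop is an alternating projection between the solenoidal-rows and
symmetric subspaces; on 32³ white noise the interior divergence norm falls
below 5% of its start after 4 cycles and below 10⁻⁶ after 20.

A spectral backend (Helmholtz projection with the centred-difference
symbol `sin(kΔ)/Δ` on a reflectively padded grid) is provided as a fast
alternative.  It annihilates the interior discrete divergence too, but it
enforces the constraint globally rather than at interior nodes only, so
its *field* differs from the exact projection by tens of percent on noise
input; the exact backend is the default and the reference.

## Evaluation metrics

Force monopole and `d_L2` use composite Simpson quadrature per axis (for
even node counts scipy's even-interval correction applies).  The
patch-resolved metrics (DTMA, tDTMA, SNR, DTMB, DMA) follow the standard
definitions over a label mask that assigns a node to a patch iff it lies
in the patch's support disk, overlaps resolving to the lowest patch index.
DMA is normalised by the *reconstructed* patch maximum, as defined —
note the asymmetry (`2×` truth gives +0.5, `½×` truth gives −1); a
truth-normalised variant is available behind a flag.  SNR's background set
is "all nodes not in any patch", the same set DTMB uses.  Metrics that are
undefined for a given truth (e.g. tDTMA on a purely normal pattern) are
reported as NaN in the aggregate report.

## Experiment drivers and problem sizes

`run_noise_sweep` simulates one pattern, then for every noise level × seed
creates **one** noisy volume (σ scaled to the volume-mean `⟨‖u‖⟩`) that
all methods share — FTTC consumes its `z = 0` layer, the direct method the
full volume — and emits a long-format table with config hash and version
for provenance.  `run_spacing_sweep` keeps the physical field of view
fixed and resamples it at each spacing (z spacing scaled proportionally),
at zero noise.  All randomness derives from the config seed.

The bundled benchmarks run at the design scale of 64×64×9 nodes
(0.4 µm spacing); the method-comparison suite uses 10 seeds per condition
and noise levels 0.2/0.5/1.0.  These sizes are the package's reference
conditions; everything is configurable upward.

## Known limitations

* With the default near-incompressible material (`ν = 0.49`) the direct
  method's dilatational term amplifies gradient noise by `2ν/(1−2ν) ≈ 49`,
  so its noisy-data metrics degrade much faster than FTTC's; at moderate
  `ν` (≈ 0.3) the two routes are far closer.  With GCV-selected λ the
  regularized FTTC background is smooth, and its SNR exceeded the direct
  method's under every condition tested here — the often-cited opposite
  ordering at high noise did not materialize under these study conditions.
* FTTC inherits the usual windowing artifacts when the displacement field
  extends beyond the field of view; its background deviation has a
  noise-independent floor from spectral ringing of the sharp-edged
  patches.
* The direct method needs `ν < 0.5` strictly and a volume input; no
  sub-surface extrapolation is attempted.
* Finite-thickness substrates, curved surfaces, nonlinear material laws,
  and image formation/tracking are out of scope.
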