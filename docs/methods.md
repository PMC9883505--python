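# Methods

## Observation model

A fluorescence acquisition is modelled as `f = T(h * u)` on a regular
grid: `u >= 0` is the true intensity image (2D, 3D, or with a leading
time axis), `h` a shift-invariant PSF, and `T` mixed Poisson-Gaussian
noise.  With quantization factor `alpha` (photons per normalized
intensity unit) and readout standard deviation `tau`, a pixel of the
blurred image `v = h * u` is observed as
`Poisson(alpha v)/alpha + N(0, tau^2)`, so its mean is `v` and its
variance `v/alpha + tau^2`.  Summed over the grid, the expected squared
residual at the true image is `||f||_1/alpha + N tau^2` — a constant
that does not depend on `u` — which is why a plain quadratic fidelity
`F(u) = 1/2 ||H u - f||^2` is a sound data term even for shot-noise
dominated data.  The simulator adds the Gaussian component after the
Poisson draw and never clips negative values; clipping would bias the
variance and break the Monte-Carlo verification of this identity.
`alpha = None`/`inf` selects the pure-Gaussian limit exactly (no Poisson
sampling at a huge rate).  All random draws come from a counter-based
Philox generator over the row-major array, so a seed reproduces the same
image on every platform.

## Regularizer

The Sparse Hessian Variation couples intensity sparsity with
second-order smoothness.  Per pixel the operator `D2_rho` stacks
`(1 - rho) u(x)` with `rho` times every second finite difference of `u`
(`d^2` slots for a `d`-dimensional image: pure differences
`u(x+e) - 2u(x) + u(x-e)` per axis, mixed forward-forward differences
for every ordered axis pair), and the regularizer is the sum over pixels
of the Euclidean norm of that vector — a group (l2,1) norm.  Two
deliberate conventions:

* **Both mixed orders are kept.**  The per-pixel vector lists `u_xy` and
  `u_yx` separately even though the discrete stencil makes them equal,
  so each mixed derivative effectively carries a `sqrt(2)` weight inside
  the norm.  Halving the list would change the calibration of `lambda`;
  the dense-matrix test oracle and the adjoint use the same convention.
* **Neumann boundaries.**  Out-of-range neighbours replicate the edge
  value (zero normal derivative).  The adjoint implements the exact
  transpose of that replication, verified by inner-product identities at
  1e-10.  Note the blur, by contrast, is periodic (FFT); the two choices
  meet the usual practice of exact-adjoint FFT convolution with
  derivative stencils that do not wrap.  A consequence worth knowing:
  restorations are exactly translation-equivariant only while content
  (and noise) stays clear of the image border, because shifting an image
  changes what the replication sees.  A replicate-pad pre-processing
  option on the convolution covers images with bright borders.

`rho` in [0, 1] interpolates from pure intensity sparsity (`rho = 0`,
the regularizer collapses to `sum |u|`) to pure second-order smoothness
(`rho = 1`).  The presets are `high` = 0.1, `moderate` = 0.6,
`weak` = 0.9, matching spot-like, mixed, and cluttered/filamentous
content respectively.  For 4D images the temporal second differences are
included with unit grid spacing; a `time_weight` knob (default 1.0)
scales every time-involving component, because whether time should be
regularized exactly like space is content-dependent and the default
treats a video as a 4D volume.

## Energy and solver

The estimate minimizes
`E(u) = 1/2 ||H u - f||^2 + lambda sum_x ||D2_rho u(x)|| + i_C(u)` with
`C` the nonnegative orthant.  The energy is convex but non-smooth; the
solver is a full-splitting primal-dual (Condat-Vu) iteration that only
ever evaluates the fidelity gradient `H^T(H u - f)`, the operators
`D2_rho` / `D2_rho^T`, the per-pixel projection of the dual variable
onto balls of radius `lambda`, and the pointwise positivity projection —
no inner loops, no operator inversions.

* **Steps.**  With `L = ||H||^2` (read off the transfer function; 1 for
  any unit-sum nonnegative kernel) and `B >= ||D2_rho||`, the scheme
  uses `sigma = tau_p = 0.9 / (L/2 + B^2)`, which satisfies the
  convergence condition `1/tau_p - sigma B^2 >= L/2`.  For `B` the
  solver uses the closed-form bound
  `B^2 = (1-rho)^2 + 16 rho^2 d^2` (each second-difference component has
  norm at most 4): the spectrum of `D^T D` is clustered at its top on
  realistic grid sizes, which makes iterative norm estimation slow,
  while an upper bound only shortens the steps slightly.  The
  power-iteration estimator (`operator_norm`) remains available and is
  validated against dense SVD on small grids.  User-supplied steps are
  checked against the same condition before iterating.
* **Initialization and stopping.**  `u0 = max(f, 0)` (warm start at the
  observation, which makes the `lambda -> 0` denoising limit exact),
  `v0 = 0`; plain iterates, no over-relaxation.  200 iterations by
  default — enough for visually converged restorations at typical sizes
  (a 512x512 2D deconvolution takes ~10 s on one CPU).  An optional
  relative-energy early stop exists but is off by default so runs are
  bit-reproducible.  Tighter optimality (the 0.1%-gap comparison against
  a brute-force convex minimizer in the test suite) uses a few thousand
  iterations on small grids; so does the dominant-regularizer limit
  `lambda -> inf`, where the dual variable must grow before smooth modes
  are extinguished.
* **Degenerate inputs.**  A constant or empty ROI is rejected by the
  weight selection; non-finite energies abort with a diagnostic; a
  kernel larger than the image is an error rather than a silent crop.

## Automatic weight selection

On intensities normalized to [0, 1] the energy is re-parameterized with
`lambda' = 1/(1 + lambda)` as
`E_lp(f, u) = lp * F + (1 - lp) * SHV_rho`.  Each candidate `lp` is
scored by restoring the ROI at the corresponding `lambda` and evaluating
`E_lp` at the minimizer; the profile is concave with a unique maximum,
attained where fidelity and regularizer balance.  The search grid is
`{0.1, ..., 0.9}` (nine points, middle 1/2 — the default weight);
hill-climbing from 1/2 stops at the first decrease, ties prefer the
smaller `lambda'` (the smoother image), and an exhaustive sweep
cross-checks unimodality, falling back to the global grid argmax with a
warning if it fails.  The selection is scale-invariant across nested
ROIs of homogeneous content, and the `F` it balances is the same
half-scaled quadratic fidelity as the energy (the alternative, an
unscaled `F`, only shifts the profile by a constant factor of 2 on the
fidelity side and was not adopted).

**What the maximum means — and its limit.**  The balanced solution is
the *smoothest acceptable* image, not the PSNR-optimal one.  On images
where the noise energy `N tau^2` is comparable to the signal mass (large
noisy fields of view — the regime automatic selection is meant for) the
balance lands near good restorations.  On a small, bright, low-noise
phantom the balance point necessarily over-regularizes: for any
[0, 1]-normalized image `F <= 0.5 sum f < (1 - rho) sum u ~ SHV` near
faithful solutions, so the crossing only happens once the signal is
substantially suppressed.  For benchmark-style PSNR scoring the package
therefore follows the benchmarking convention of restoring at several
weights and reporting the best score; the minimax selection is kept for
its intended interactive use and its structural properties (unimodality,
hill-climb optimality, ROI-scale stability) are what the tests assert.
A 3x3 preview matrix (rows: selected `lambda'` and neighbours, columns:
the three sparsity presets, with the default `lambda' = 1/2` and the
mirrored `1 - lambda'*` cells flagged) supports that interactive use.

## PSF models

All kernels are nonnegative, unit-sum, odd-sized, peak-centered; widths
are in pixels except for the physical-unit Gibson-Lanni model.

* **Gaussian** (2D/3D, isotropic in XY, separate `sigma_z`): sampled at
  pixel centers, not integrated over pixels — at `sigma >= 1` the
  difference is far below the noise in any experiment here.  Default
  support `2 ceil(4 sigma) + 1` per axis keeps the truncated mass below
  ~5e-4.
* **Lorentzian 2D** `(1 + (r/gamma)^2)^-1` with `gamma` the half-width —
  a heavier-tailed alternative for depletion-based modalities.
* **Gibson-Lanni 3D**: scalar Kirchhoff integral over the pupil with the
  defocus phase `z sqrt(n_i^2 - NA^2 s^2)` plus a specimen
  index-mismatch term driven by an optional depth (default 0).
  Trapezoid quadrature doubles the pupil sampling until the kernel
  changes by less than 1e-4 (error otherwise).  Only `n_planes_kept`
  axial planes around focus are retained and renormalized, reflecting
  how thin truncated kernels are used in practice.  The default optical
  parameters (NA 1.4, 520 nm, indices 1.515, 100 nm pixels, 250 nm
  steps) are generic placeholders, not calibrated values.  With matched
  indices the model is axially symmetric and its focal plane reproduces
  the Airy pattern (first minimum at `0.61 lambda / NA`), which the
  tests verify.
* **Dirac**: the identity kernel; deconvolution with it *is* denoising,
  and the pipelines exploit that equivalence literally (bit-identical
  outputs).

## Pipelines

Strategy modes mirror the decision flow a practitioner walks:
`denoise{2d,3d,4d}`, `deconv{2d,3d}`, `deconv_pbyp` (each XY section
deconvolved independently with a 2D PSF — preferable when the 3D PSF is
poorly characterized), `denoise_then_deconv{3d,_pbyp}`, and
`denoise4d_then_deconv3d_per_frame` for videos (denoise the whole T-Z
volume with the 4D operator, then deconvolve each frame in 3D).
Intensities are normalized once per run by the global maximum (so
temporal dynamics such as bleaching are preserved across frames — a
per-frame normalization would erase them) and denormalized on output;
restoration is therefore scale-equivariant.  Automatic `lambda'`
selection runs once per stage on a 2D ROI (user-specified or a centered
crop of up to 64x64 of the middle plane/frame), with a 3D PSF reduced to
2D by axial summation for the selection only — keeping plane and frame
outputs mutually comparable.  Multichannel data is processed one channel
per run; there is no joint regularization.

## Synthetic data

The phantom generator produces the two structural regimes the method
targets, plus their mixture: *spots* (vesicle-like Gaussian blobs,
truncated at 4 sigma and rejection-sampled to disjoint supports, so the
background is exactly zero — the "highly sparse" regime) and *filaments*
(smoothed random-walk curves — the "weakly sparse" regime).  Defaults
(64x64, 10 spots, blob sigma 1.2 px, amplitudes uniform in [0.5, 1])
emulate diffraction-limited vesicles at typical densities.  Degradation
is Gaussian blur (`sigma_xy` in {1, 1.25, 1.5}) followed by the noise
model (`tau` in {0.01, 0.02, 0.04}, optional Poisson component).  What
the phantoms deliberately lack: textured cytoplasmic background,
spatially varying blur, detector fixed-pattern noise, and saturation —
so green tests demonstrate correctness of the algorithm and its
implementation on in-model data, not performance claims on real
micrographs.

Quality metrics: PSNR with peak fixed at 1 (images normalized; the
reference owns the normalization, so the metric is not symmetric in its
arguments), and ROI-power SNR (mean squared intensity of a signal ROI
over that of a disjoint background ROI; zero background power is an
error, not infinity).

## Problem sizes in the automated checks

The test suite and the acceptance script use 8x8 instances for dense /
brute-force oracle comparisons (where an explicit matrix or an L-BFGS-B
minimization is tractable and exact), 64x64 phantoms for the
restoration protocol and weight selection, and one 512x512 run of the
default configuration — sizes chosen so each oracle is computable
exactly while the protocol still exercises the full pipeline.

## Known limitations

* Shift-invariant blur only; no spatially varying PSF.
* The periodic convolution can wrap bright borders into the opposite
  edge; use the padding option for such images.
* The minimax weight targets visual acceptability, not PSNR optimality,
  and over-smooths small bright low-noise images (see above).
* The Gibson-Lanni model is scalar (paraxial-pupil) — no vectorial
  high-NA effects — and its defaults are uncalibrated placeholders.
* No acceleration (FISTA-style) or GPU path; 4D denoising of large
  videos is CPU-bound.
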