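# shvrestore

Denoising and deconvolution of 2D / 3D / 4D fluorescence microscopy
images with a Sparse Hessian Variation (SHV) regularizer, a
positivity-constrained quadratic-fidelity energy, and a full-splitting
primal-dual solver — plus automatic selection of the regularization
weight.

## Who this is for

Microscopists and image-analysis engineers who need to recover
structure from noisy, blurred fluorescence acquisitions (confocal,
light-sheet, STED, widefield) at low illumination doses, where photon
shot noise and out-of-focus background dominate, and who want one
algorithm that covers denoising (Dirac PSF), 2D/3D deconvolution,
plane-by-plane deconvolution when the 3D PSF is poorly known, and
chained denoise-before-deconvolve pipelines for videos.

## The model

An observation `f` is a blurred, noisy version of the true image `u`:

    f = T(h * u)

with `h` the point spread function and `T` mixed Poisson-Gaussian noise
(`Poisson(alpha v)/alpha + N(0, tau^2)` per pixel, whose variance is
`v/alpha + tau^2`).  The restoration is the minimizer of the convex
energy

    E(u) = 1/2 ||H u - f||_2^2  +  lambda * SHV_rho(u)  +  i_{u >= 0}(u)

where the Sparse Hessian Variation regularizer

    SHV_rho(u) = sum_x sqrt( rho^2 ||Hess u(x)||_F^2 + (1 - rho)^2 u(x)^2 )

jointly sparsifies intensities and second derivatives: it removes smooth
background and noise without the stair-casing of first-order total
variation.  `rho` is exposed as three presets — `high` (0.1) for
spot-like content, `moderate` (0.6), `weak` (0.9) for cluttered
filamentous content.  The energy is minimized with a Condat-Vu
primal-dual scheme (gradient step on the fidelity, per-pixel ball
projection for the dual of the group norm, pointwise positivity
projection; 200 iterations by default).  The smoothing weight can be
selected automatically: with `lambda' = 1/(1 + lambda)`, the profile
`lambda' -> lambda' F + (1 - lambda') SHV` evaluated at the minimizers
has a unique maximum, found by hill-climbing from `lambda' = 1/2`.

## Worked example

```python
import numpy as np
import shvrestore as sr

# a 64x64 "vesicles" phantom: 10 bright spots over a dark background
spec = sr.PhantomSpec(kind="spots", shape=(64, 64), n_objects=10,
                      object_scale=1.2, seed=7)
clean = sr.make_phantom(spec)

# degrade: Gaussian blur sigma_xy = 1 px + Gaussian noise tau = 0.01
psf = sr.gaussian_psf(sigma_xy=1.0)
noisy = sr.degrade(clean, psf, sr.DegradationParams(alpha=None, tau=0.01, seed=11))

restored, trace = sr.restore(noisy, psf, sr.RegularizationParams(rho=0.1, lam=0.005))
print(f"PSNR degraded  {sr.psnr(clean, noisy):.2f} dB")
print(f"PSNR restored  {sr.psnr(clean, restored):.2f} dB")
```

prints

```
PSNR degraded  30.37 dB
PSNR restored  42.73 dB
```

i.e. deconvolution plus denoising recovers about 12 dB on this phantom:
the spots sharpen back to their unblurred widths and the background
returns to (near) zero, which is what the intensity term of the
regularizer is for.

The same operations are available from a shell:

```bash
shvrestore simulate --kind spots --shape 64x64 --sigma-xy 1.0 --tau 0.01 \
    --seed 7 --out-clean clean.tif --out-degraded noisy.tif
shvrestore run --mode deconv2d --input noisy.tif --output restored.tif \
    --psf gaussian --sigma-xy 1.0 --sparsity high --lambda 0.005
shvrestore metrics --reference clean.tif --test restored.tif
```

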