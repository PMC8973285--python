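# Methods

## The imaging model

A digital autoradiography (DAR) frame records the distribution of a
radioisotope in a tissue section through a phosphor plate read out in
"digital light units" (DLU). The measurement chain is modelled per pixel
`p` as

    R_p = alpha * Q_p + N_p,      Q_p ~ Poisson[ (X * h)_p + b ],
    N_p ~ Normal(0, sigma_g^2),

where `X` is the clean activity map, `h` an isotropic point-spread function
set by the isotope's particle range and the plate/reader optics, `b` a
spatially homogeneous background count rate, `alpha` the reader gain
(DLU/count) and `sigma_g` the readout-noise SD. Pixels are independent.
The background rate of a phosphor plate is well above 3 counts, so the
Poisson background is close to Gaussian and the total background-plus-readout
noise can be reorganized into a single Gaussian component with

    mu_N = alpha * b,        sigma_N^2 = alpha^2 * b + sigma_g^2,

riding on the Poisson-distributed signal `alpha * P[X * h]`. All later
stages work with (mu_N, sigma_N) only; `estimate_noise` warns when the
implied `b` is at or below 3, where this reorganization degrades.

## Noise-parameter estimation

Non-tissue regions contain only this Gaussian background and look alike.
The image is tiled into non-overlapping 8x8 patches; each patch is reduced
to its (mean, SD) pair; the pairs are standardized robustly — median and
1.4826xMAD per feature — and clustered with DBSCAN (defaults eps=0.5,
min_samples=5 in standardized units). Among clusters holding at least 10%
of all patches, the one with the lowest mean intensity is the background;
mu_N and sigma_N are then the mean and sample SD over the *pixels* of those
patches (patch summaries would waste sample size and bias the SD on small
patches).

Robust rather than z-score standardization matters: on specimens with a
small number of very bright patches the patch-feature variance is dominated
by those patches, the background/faint-tissue separation is compressed
below eps, and DBSCAN chains tissue into the background cluster. Scaling
by the MAD — which reflects the majority (background) spread — keeps the
clusters separated. Patch size 8 balances feature stability against patch
purity; all three knobs are exposed.

## The restoration loop

Given (mu_N, sigma_N), restoration alternates, per outer iteration:

1. **E-step** — replace each raw pixel by a nonnegative pseudo-count, the
   expected Poisson count given the observation and the current blurred
   estimate `lam = x*h`. Default (`gaussian_approx`) is the posterior mean
   under a joint Gaussian approximation,

       E_p = max(0, lam_p + (a*lam_p / (a^2*lam_p + sigma_N^2)) * (R_p - mu_N - a*lam_p)),

   which interpolates between trusting the data (high-count pixels) and
   trusting the prior mean (background pixels). The `shifted_poisson`
   alternative `E_p = max(0, (R_p - mu_N)/a + sigma_N^2/a^2)` treats the
   Gaussian part as extra Poisson counts; it is retained as the reference
   ablation.
2. **M-step, image** — `inner_iters_x` (default 5) updates, each a
   multiplicative Richardson-Lucy step `x <- x * (h~ conv (E / (x*h)))`
   followed, when the image penalty is active, by an implicit
   half-quadratic smoothing step (below).
3. **M-step, PSF** — `inner_iters_h` (default 5) multiplicative updates of
   the kernel on its support window with an L2 shrinkage factor
   `1/(1 + 2*lambda_h*h)`, then exact radial averaging (circular symmetry
   is physical: emission is isotropic), then renormalization to unit sum.

The loop stops when the relative L1 change of `x` per outer iteration drops
below `tol` (1e-4) or after `max_outer_iters` (100). A penalized objective
(Poisson negative log-likelihood of the pseudo-counts plus the penalties)
is recorded each outer iteration; because the E-step is approximate the
trace is non-increasing only up to small (~1e-4 relative) fluctuations, and
the tests assert exactly that: >= 95% of steps non-increasing within a 0.1%
band and an overall decrease.

### Image regularization: Hessian-Frobenius, implicitly

The image penalty is the Hessian-Frobenius norm
`sum_p sqrt(x_xx^2 + 2 x_xy^2 + x_yy^2 + eps^2)` (eps = 1e-8), a
second-order analogue of total variation that favours piecewise-*smooth*
rather than piecewise-constant images and therefore avoids TV's staircase
artifact on intensity ramps — the typical profile of tracer uptake in
tissue. Second differences are evaluated on interior stencils and
contribute zero at border pixels, so affine images are exactly penalty-free
(a mirror-boundary stencil would penalize a plain ramp at the borders).

The penalized image update deliberately does *not* divide the RL step by
`1 + lambda_x * grad`: for this penalty the gradient is essentially
sign-only on oscillatory modes (the sqrt normalizes its magnitude), and the
asymmetric pair product `1/(1+a) * 1/(1-a) > 1` of the one-sided
multiplicative correction *amplifies* checkerboard noise at any useful
weight — we verified the roughness of the iterate grows without bound for
lambda_x >= 0.05 under that scheme. Instead, after each RL step the
penalty is applied as an implicit half-quadratic proximal step: freezing
the normalization weights at the current iterate turns the penalty into a
quadratic form `(1/2)<v, A_w v>` whose gradient matches the true penalty
gradient there, and

    (I + lambda_eff * A_w) v = x_rl

is solved by a short conjugate-gradient run (12 iterations; the operator is
`I` plus a positive-semidefinite weighted biharmonic, so CG converges
fast). `lambda_eff = lambda_x * mean(x)` and the weight floor
`1e-3 * mean(x)` are normalized by the mean intensity so smoothing strength
is invariant to rescaling the image — and hence to the gain `alpha`. The
implicit step is unconditionally stable, which is what lets the staircase
comparison (below) be run at meaningful weights. The TV ablation uses the
same machinery with first-difference weights.

### PSF model and initialization

The initial kernel follows the inverse-square law for an isotropic emitter
at height `t` (the emulsion-to-phosphor gap, in pixels) above the plate:
`k(x, y) ~ t / (t^2 + x^2 + y^2)^(3/2)`, sampled at pixel centers and
normalized. This is the unique radially symmetric flux density of a point
source at distance `t` when only geometric spreading is considered; its
FWHM is about `1.53 t`. The profile is heavy-tailed — the enclosed mass
grows as `1 - t/sqrt(t^2 + r^2)`, so capturing 99.5% of it would need a
support radius near `200 t`. The default truncation radius is therefore
`ceil(4t)` (about 76% of the untruncated mass, renormalized); the far tail
is indistinguishable from homogeneous background at realistic count levels.

The initial activity estimate is `x0 = max(R - mu_N, eps)/alpha` with
`eps = 1e-6 * max(R)`: subtracting the known background mean from the
initialization speeds convergence; `init="raw"` restores the plain
`max(R, eps)/alpha` rule.

Blind PSF estimation is only well-posed when the scene constrains it.
Point-dominated scenes identify `h` well (the tests require FWHM recovery
within 25% there); extended smooth scenes do not, and the estimated kernel
mostly absorbs whatever blur the image penalty has not attributed to `x`.
`lambda_h` sets the balance: at 0 the kernel collapses to a delta (the
classic blind-deconvolution failure mode), at very large values it flattens
toward uniform. The default 2.5, like `lambda_x = 0.01`, was fixed by a
sweep on simulated ground truth (RMSE/SSIM over the four phantom families,
plus kernel-FWHM recovery on the point family) — the same
tune-on-simulation procedure a practitioner would use, run once via the
`sweep`/benchmark harness.

### Gain invariance

In the pure Poisson-deconvolution regime (sigma_N = 0) the E-step reduces
to `R/alpha` and the whole pipeline is exactly equivariant: doubling
`alpha` scales the output by 1/2 with an identical pattern, so the gain
never needs calibration. With sigma_N > 0 the Gaussian-approximation
E-step depends on `alpha` through the posterior gain and the equivariance
is only approximate (pattern correlation ~0.97 on the point fixture when
alpha doubles against fixed noise estimates); total recovered activity
still scales as 1/alpha. The tests assert the exact property at
sigma_N = 0 and the approximate one under estimated noise.

## Quality metrics

* **STDB** — sample SD over background pixels; the noise-level metric.
* **CNR** — `(mean_signal - mean_background) / STDB`. The denominator
  convention (background SD) is the most common one and is the package's
  choice; zero STDB returns +inf with a warning.
* **RMSE / SNR / SSIM** — ground-truth metrics for simulations.
  `snr_db = 10 log10(sum t^2 / sum (t - e)^2)` uses the clean signal's
  power. SSIM uses the standard constants (uniform 7x7 window, K1=0.01,
  K2=0.03) with the dynamic range taken from the first (reference) image.
* **Effective resolution** — decorrelation analysis: the spectrum `F` is
  correlated with its phase-only version masked to disks of increasing
  radius; the correlation `d(r)` peaks at the highest frequency where
  signal still dominates noise. The analysis is repeated over a bank of 10
  Gaussian high-pass pre-filters (sigma geometrically spaced over
  0.05–1 in Nyquist units) plus the unfiltered curve, over 50 radii; the
  cutoff `k_c` is the largest peak position (prominence >= 1e-3) across the
  bank and the reported figure is the equivalent FWHM `2/k_c` pixels. The
  input is mean-subtracted and cosine-apodized at the borders to suppress
  spectral leakage. This measures *usable*, not theoretical, resolution:
  on a noiseless point grid blurred to FWHM 6 px it reports ~5.6 px, and it
  degrades (grows) as SNR falls.
* **Fusion index** — fraction of total activity on an anatomical surface
  mask (bone surfaces, where a bone-seeking alpha emitter adsorbs); with
  **high-activity SSIM** (SSIM between the top-decile activity mask and the
  anatomical mask) it quantifies anatomical agreement.

## The synthetic-data generator

`make_phantom` provides four families: isolated single-pixel point sources
(resolution studies), bar groups of graded width (1–6 px), bone-section
rings with ~95% of activity on 2-px ring boundaries plus faint interior
uptake (the alpha-emitter bone-biopsy geometry), and smooth random blobs.
`simulate_dar` draws the forward model exactly (Poisson field first, then
the Gaussian field, one generator per call seeded by the caller), and
`scale_to_peak_counts` sets the signal level by scaling the phantom so the
blurred signal peaks at a stated count — the knob that sets SNR
independently of geometry.

The generator emulates the statistics of the measurement chain, not the
content of real autoradiographs: real frames add spatially varying
background (the model assumes homogeneous `b`), plate-scanner artifacts,
isotope-specific PSF shapes beyond the inverse-square family, and tissue
textures richer than these phantoms. Passing tests therefore validate the
estimation machinery under the stated model, not performance on any
particular real dataset.

## Study conditions for the headline figures

`scripts/acceptance.py` reruns two fold-improvement studies end to end
(simulate -> estimate noise -> blind restore at defaults -> decorrelation
resolution on raw and restored; median over 10 seeds at 256x256):

* broad PSF (gap 8 px, kernel FWHM ~12 px), low signal (peak ~30 counts),
  b=10, sigma_g=3, bar phantoms — the positron-range-style condition;
* narrow PSF (gap 2 px, FWHM ~3 px), moderate signal (peak ~200 counts),
  b=10, sigma_g=2, bone-section phantoms — the alpha-emitter condition.

256x256 at 10 seeds keeps a full study within minutes on one CPU while
leaving >= 3 resolvable octaves between kernel FWHM and image size.

## Numerical choices and degenerate inputs

Double precision throughout; convolutions by FFT on symmetric
(edge-replicating) padding, which matches `scipy.ndimage` mode="reflect"
and makes constant images exact RL fixed points; denominators clipped at
1e-12; penalty smoothing constant 1e-8; kernel invariants (nonnegative,
unit sum to 1e-9, central symmetry) enforced on construction. Non-finite
values during iteration raise immediately, naming the outer iteration.
Degenerate inputs (constant images for resolution, empty masks, zero total
activity, all-signal images for noise estimation) raise descriptive errors
rather than returning silently wrong numbers.

## Known limitations

* Blind PSF recovery on extended smooth scenes is ill-posed; the reported
  kernel there reflects the regularization as much as the data.
* The homogeneous-background assumption is structural; spatially varying
  `b` biases mu_N and everything downstream.
* The objective is non-convex (blind deconvolution); convergence is to a
  local solution and initialization-dependent.
* The decorrelation cutoff is quantized by the radius grid (50 radii), so
  resolution estimates move in ~2% steps of Nyquist; ratios of coarse
  values inherit that granularity.
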