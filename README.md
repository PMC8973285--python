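# pgpem — blind restoration of digital autoradiography images

Digital autoradiography (DAR) maps the distribution of a radiopharmaceutical
in a tissue section by exposing a phosphor plate and reading it out with a
scanning laser. The images are blurred by an isotope-dependent point-spread
function that cannot practically be calibrated, and carry mixed noise: a
Poisson component from radioactive counting on top of a homogeneous
background rate, and Gaussian readout noise. `pgpem` restores such images
*blindly* — jointly estimating the clean activity map and the PSF from a
single frame — for people doing preclinical tracer work or small-scale
dosimetry of targeted alpha/beta therapy, and for anyone who needs a tested
mixed Poisson–Gaussian restoration baseline on synthetic data.

## The model and the algorithm

A frame is modelled per pixel as

    R_p = α·Q_p + N_p,    Q_p ~ Poisson[(X∗h)_p + b],    N_p ~ N(0, σ_G²),

with gain α, activity map X, isotropic PSF h and background rate b. Since
b ≫ 3 in practice, background-plus-readout noise reorganizes into a single
Gaussian N(μ_N, σ_N²) with μ_N = αb and σ_N² = α²b + σ_G², estimated from
the image itself: non-overlapping patches are reduced to (mean, SD)
features, DBSCAN finds the dense low-intensity cluster of mutually similar
background patches, and μ_N/σ_N come from those pixels.

Restoration is a penalized expectation-maximization loop: the E-step
removes the Gaussian component by computing the expected Poisson count per
pixel; the M-step runs multiplicative Richardson–Lucy updates jointly on X
and h, with an L2 penalty on h (λ_h, preventing the blind kernel from
collapsing to a delta) and a Hessian–Frobenius penalty on X (λ_X, applied
as an implicit half-quadratic step; it suppresses noise without the
staircase artifact of total variation). With noise and penalties switched
off and the kernel fixed, the loop reduces exactly to Richardson–Lucy.

Quality metrics cover both reference-free assessment — background SD
(STDB), contrast-to-noise ratio (CNR), and a decorrelation-based effective
resolution (the highest frequency with signal above noise, reported as an
equivalent FWHM in pixels) — and ground-truth comparison (RMSE, SNR, SSIM),
plus a fusion index (fraction of activity on an anatomical surface mask)
for bone-seeking alpha emitters.

See `docs/methods.md` for assumptions, parameter defaults and their
rationale, numerical choices, and known limitations.

## Worked example

`examples/03_blind_restoration.py` simulates a bone-section phantom
(activity on ring boundaries, peak 200 counts, b = 10, σ_G = 2, narrow
inverse-square PSF), estimates the noise, restores blindly at defaults and
prints:

```
ran 100 outer iterations, converged=False
estimated PSF FWHM 3.98 px (true 3.19)
raw       STDB    5.704   CNR     4.78   eff. FWHM   4.55 px
restored  STDB    0.196   CNR   213.70   eff. FWHM   2.00 px
vs truth: RMSE 37.87   SNR 4.13 dB   SSIM 0.975
fusion index raw 0.136 -> restored 0.939 (share of activity on the bone surface)
```

Reading the numbers: restoration flattens the background (STDB drops
~30-fold, hence the large CNR), sharpens the usable resolution from 4.6 px
to the 2 px Nyquist floor (a ~2.3-fold gain), and concentrates activity
back onto the bone-surface mask (fusion index 0.14 → 0.94). The
other examples cover the forward simulator and its background moments
(`01`), noise-parameter recovery (`02`), and the ablation benchmark (`04`).

A thin CLI mirrors the library for shell use — `pgpem simulate`,
`estimate-noise`, `restore`, `evaluate`, `profile`, `benchmark`, `sweep` —
each writing a JSON run manifest with the resolved configuration and seeds
so runs are reproducible.

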