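"""Background-noise parameter estimation from a single raw DAR image.

Because the background count rate ``b`` of a phosphor plate comfortably
exceeds 3, the Poisson background is well approximated by a Gaussian, and the
combined background-plus-readout noise is itself Gaussian with

    mu_N = alpha * b,        sigma_N^2 = alpha^2 * b + sigma_g^2.

Non-tissue areas carry only this noise and look alike, so background pixels
are found by tiling the image into patches, describing each patch by its
(mean, SD) pair, and density-clustering the standardized features with
DBSCAN: the lowest-intensity dense cluster is the background, and mu_N /
sigma_N are estimated from its pixels directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from .simulate import RawImage

__all__ = [
    "NoiseParams",
    "PatchTable",
    "NoiseEstimationError",
    "extract_patches",
    "cluster_background",
    "estimate_noise_params",
    "estimate_noise",
    "gaussian_approx_valid",
]


class NoiseEstimationError(RuntimeError):
    """Raised when background statistics cannot be estimated."""


@dataclass
class NoiseParams:
    """Gaussian background statistics in digital light units."""

    mu_n: float
    sigma_n: float
    n_background_pixels: int

    def __post_init__(self) -> None:
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be nonnegative")
        if self.n_background_pixels < 1:
            raise ValueError("n_background_pixels must be >= 1")

    def implied_b(self, alpha: float = 1.0) -> float:
        """Background count rate implied by mu_n at the given gain."""
        return self.mu_n / alpha


@dataclass
class PatchTable:
    """Per-patch features over a non-overlapping tiling of the image.

    ``label`` is -1 for density outliers, a nonnegative cluster id otherwise,
    and ``None`` before clustering; ``is_background`` flags the selected
    background cluster.
    """

    patch_index: np.ndarray      # (n, 2) grid coordinates
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    patch_size: int
    label: np.ndarray | None = None
    is_background: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.feature_mean)


def extract_patches(image: RawImage | np.ndarray, patch_size: int = 8) -> PatchTable:
    """Tile the image into non-overlapping square patches and featurize them.

    Trailing rows/columns that do not fill a whole patch are dropped.  Each
    patch contributes its pixel mean and SD (population SD, ddof=0).
    """
    pixels = image.pixels if isinstance(image, RawImage) else np.asarray(image, dtype=float)
    patch_size = int(patch_size)
    if patch_size < 4:
        raise ValueError("patch_size must be >= 4")
    ny, nx = pixels.shape[0] // patch_size, pixels.shape[1] // patch_size
    if ny < 4 or nx < 4:
        raise ValueError("image too small: need at least a 4x4 grid of patches")
    tiles = pixels[: ny * patch_size, : nx * patch_size].reshape(
        ny, patch_size, nx, patch_size
    ).transpose(0, 2, 1, 3).reshape(ny * nx, -1)
    gy, gx = np.mgrid[0:ny, 0:nx]
    return PatchTable(
        patch_index=np.column_stack([gy.ravel(), gx.ravel()]),
        feature_mean=tiles.mean(axis=1),
        feature_sd=tiles.std(axis=1),
        patch_size=patch_size,
    )


def cluster_background(patches: PatchTable, eps: float = 0.5, min_pts: int = 5,
                       min_cluster_frac: float = 0.10) -> PatchTable:
    """Cluster patch features with DBSCAN and flag the background cluster.

    Features are standardized robustly (median / scaled MAD) so intensity
    and spread are on comparable scales: because background patches are the
    majority, the MAD reflects the background's own spread and a handful of
    very bright tissue patches cannot compress the scale the way a plain
    z-score would.  Among clusters holding at least ``min_cluster_frac`` of
    all patches, the one with the lowest mean patch intensity is declared
    background.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    feats = np.column_stack([patches.feature_mean, patches.feature_sd])
    med = np.median(feats, axis=0)
    mad = 1.4826 * np.median(np.abs(feats - med), axis=0)
    mad[mad == 0] = 1.0
    z = (feats - med) / mad
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(z)
    patches.label = labels

    candidates = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        members = labels == lab
        if members.sum() >= min_cluster_frac * len(labels):
            candidates.append((patches.feature_mean[members].mean(), lab))
    if not candidates:
        raise NoiseEstimationError(
            "no dense cluster holds >= {:.0%} of patches; adjust eps/min_pts".format(min_cluster_frac)
        )
    background_label = min(candidates)[1]
    patches.is_background = labels == background_label
    return patches


def estimate_noise_params(image: RawImage | np.ndarray, patches: PatchTable) -> NoiseParams:
    """Estimate mu_N / sigma_N from the pixels of the background patches.

    Pixel-level statistics (not patch summaries) are used, which maximizes
    the sample and avoids small-patch SD bias.
    """
    if patches.is_background is None:
        raise NoiseEstimationError("background patches not flagged; run cluster_background first")
    pixels = image.pixels if isinstance(image, RawImage) else np.asarray(image, dtype=float)
    ps = patches.patch_size
    mask = np.zeros(pixels.shape, dtype=bool)
    for (gy, gx) in patches.patch_index[patches.is_background]:
        mask[gy * ps:(gy + 1) * ps, gx * ps:(gx + 1) * ps] = True
    vals = pixels[mask]
    if vals.size < 100:
        raise NoiseEstimationError(f"only {vals.size} background pixels; need >= 100")
    return NoiseParams(mu_n=float(vals.mean()), sigma_n=float(vals.std(ddof=1)),
                       n_background_pixels=int(vals.size))


def gaussian_approx_valid(b_hat: float) -> bool:
    """Whether the Poisson background is Gaussian-like (b strictly above 3)."""
    if not np.isfinite(b_hat):
        raise ValueError("b_hat must be finite")
    return bool(b_hat > 3)


def estimate_noise(image: RawImage | np.ndarray, patch_size: int = 8,
                   eps: float = 0.5, min_pts: int = 5, alpha: float = 1.0) -> NoiseParams:
    """One-call pipeline: patches -> DBSCAN -> pixel statistics.

    Emits a warning (never a failure) when the implied background rate is too
    low for the Gaussian reorganization to be trustworthy.
    """
    patches = extract_patches(image, patch_size=patch_size)
    patches = cluster_background(patches, eps=eps, min_pts=min_pts)
    params = estimate_noise_params(image, patches)
    if not gaussian_approx_valid(params.implied_b(alpha)):
        warnings.warn(
            "estimated background rate b_hat <= 3: the Gaussian approximation "
            "of the Poisson background may be inaccurate",
            stacklevel=2,
        )
    return params
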