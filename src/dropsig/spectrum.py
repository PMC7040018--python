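"""Rotation-invariant angular log-power-spectrum features.

The edge-magnitude image is resampled onto a polar (radius x angle) grid
about the droplet centre, and per radial ring the magnitude of the discrete
Fourier transform along the angle gives the angular power spectrum in
cycles per revolution.  Because the DFT magnitude is invariant to circular
shifts, the resulting feature matrix is immune to rotations of the droplet
about its centre — the property the whole feature design exists for.

Grid defaults are 48 radial bins x 103 angular samples; the first radial
ring is discarded and only the first 52 frequency columns (the non-redundant
half of the 103-point spectrum) are kept, giving 47 x 52 = 2444 features
per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from sklearn.base import BaseEstimator, TransformerMixin

from .preprocess import preprocess_image

__all__ = [
    "PolarImage",
    "SpectralFeatures",
    "find_centre",
    "to_polar",
    "log_power_spectrum",
    "truncate_features",
    "average_and_normalise",
    "image_features",
    "SpectralFeatureExtractor",
]

N_RADIAL = 48
N_THETA = 103
#: additive floor inside both logarithms (values can be exactly zero)
LOG_EPS = 1e-6


@dataclass
class PolarImage:
    """Deposit intensity on an (n_r x n_theta) polar grid about the centre."""

    values: np.ndarray  # (n_r, n_theta)
    centre: tuple[float, float]  # (row, col)
    radius: float

    @property
    def n_r(self) -> int:
        return self.values.shape[0]

    @property
    def n_theta(self) -> int:
        return self.values.shape[1]


@dataclass
class SpectralFeatures:
    """Per-image log power spectrum and its truncated feature vector."""

    gamma: np.ndarray  # (n_r, n_theta) log |angular DFT|
    eps: float = LOG_EPS
    truncated: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.truncated = truncate_features(self.gamma)


def find_centre(ch: np.ndarray, min_area_frac: float = 0.01) -> tuple[tuple[float, float], float]:
    """Locate the droplet: centroid and equivalent radius of the deposit.

    The deposit is darker than the pale background in the red channel, so
    we smooth, Otsu-threshold, keep the largest below-threshold connected
    component, and report its centroid and sqrt(area/pi).
    """
    ch = np.asarray(ch, dtype=float)
    smooth = ndimage.gaussian_filter(ch, sigma=2.0)
    thr = filters.threshold_otsu(smooth)
    # bright cracks inside the deposit fall above threshold; fill the holes
    fg = ndimage.binary_fill_holes(smooth < thr)
    labels = measure.label(fg)
    if labels.max() == 0:
        raise ValueError("no deposit found: threshold produced no foreground")
    regions = measure.regionprops(labels)
    best = max(regions, key=lambda r: r.area)
    if best.area < min_area_frac * ch.size:
        raise ValueError(
            f"largest component covers {best.area / ch.size:.2%} of the image, "
            f"below the {min_area_frac:.0%} floor"
        )
    centre = (float(best.centroid[0]), float(best.centroid[1]))
    radius = float(np.sqrt(best.area / np.pi))
    return centre, radius


def to_polar(
    ch: np.ndarray,
    centre: tuple[float, float],
    radius: float,
    n_r: int = N_RADIAL,
    n_theta: int = N_THETA,
) -> PolarImage:
    """Bilinearly resample onto radii (i+1)*radius/n_r and angles 2*pi*j/n_theta.

    Samples falling outside the raster take the nearest border value.
    """
    ch = np.asarray(ch, dtype=float)
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if n_r < 2 or n_theta < 4:
        raise ValueError("polar grid too small: need n_r >= 2 and n_theta >= 4")
    r = (np.arange(n_r) + 1.0) * radius / n_r
    theta = 2.0 * np.pi * np.arange(n_theta) / n_theta
    rows = centre[0] + r[:, None] * np.sin(theta)[None, :]
    cols = centre[1] + r[:, None] * np.cos(theta)[None, :]
    values = ndimage.map_coordinates(ch, [rows, cols], order=1, mode="nearest")
    return PolarImage(values=values, centre=tuple(centre), radius=float(radius))


def log_power_spectrum(
    pol: PolarImage, eps: float = LOG_EPS, outer_log: bool = True
) -> SpectralFeatures:
    """Angular log power spectrum, Gamma[i, w] = log(|FFT_theta(log(P[i] + eps))| + eps).

    Per radial ring the values (a Laplacian magnitude, hence >= 0) are
    log-compressed, Fourier-transformed along the angle, and the magnitude
    is log-compressed again.  Frequencies are indexed 0..n_theta-1 in
    cycles per revolution.  ``outer_log=False`` returns the linear power
    spectrum instead (exposed for comparison; not validated).
    """
    values = np.asarray(pol.values, dtype=float)
    if (values < 0).any():
        raise ValueError("polar values must be non-negative (Laplacian magnitude)")
    spectrum = np.abs(np.fft.fft(np.log(values + eps), axis=1))
    gamma = np.log(spectrum + eps) if outer_log else spectrum
    return SpectralFeatures(gamma=gamma, eps=eps)


def truncate_features(gamma: np.ndarray) -> np.ndarray:
    """Drop the innermost radial row and keep the first half of the bandwidth.

    The first ring carries negligible radial information and the upper half
    of the 103-point spectrum mirrors the lower, so a 48x103 matrix becomes
    a row-major flattened 47x52 = 2444 vector.
    """
    gamma = np.asarray(gamma)
    if gamma.ndim != 2:
        raise ValueError(f"expected a 2-D spectrum matrix, got shape {gamma.shape}")
    n_r, n_theta = gamma.shape
    n_keep = int(np.ceil(n_theta / 2))  # 52 of 103
    return gamma[1:, :n_keep].reshape(-1)


def average_and_normalise(vectors: np.ndarray, k: int | None = None) -> np.ndarray:
    """Average the first k replicate vectors, then min-max rescale to [0, 1].

    Replicates are taken in the order supplied (acquisition order).  A
    constant average maps to all zeros.
    """
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if k is None:
        k = vectors.shape[0]
    if not 1 <= k <= vectors.shape[0]:
        raise ValueError(f"k must be in 1..{vectors.shape[0]}, got {k}")
    mean = vectors[:k].mean(axis=0)
    lo, hi = mean.min(), mean.max()
    if hi == lo:
        import warnings

        warnings.warn("constant feature vector: min-max normalisation yields zeros")
        return np.zeros_like(mean)
    return (mean - lo) / (hi - lo)


def image_features(
    img: np.ndarray,
    alpha: float = 200.0,
    sigma: float = 0.01,
    n_r: int = N_RADIAL,
    n_theta: int = N_THETA,
    eps: float = LOG_EPS,
    context_px: int | None = 4,
) -> np.ndarray:
    """RGB droplet photo -> truncated 2444-long spectral feature vector."""
    edge = preprocess_image(img, alpha=alpha, sigma=sigma, context_px=context_px)
    centre, radius = find_centre(np.asarray(img)[:, :, 0].astype(float))
    pol = to_polar(edge, centre, radius, n_r=n_r, n_theta=n_theta)
    return log_power_spectrum(pol, eps=eps).truncated


class SpectralFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer: iterable of RGB droplet images -> feature matrix.

    Stateless (fit is a no-op); exists so the image chain composes with
    sklearn pipelines.  Parameters mirror :func:`image_features`.

    Parameters
    ----------
    alpha : blue/green crack-detection threshold (0-255).
    sigma : Gaussian low-pass width, cycles per pixel.
    n_r, n_theta : polar grid size (defaults 48 x 103).
    eps : additive floor inside the two logarithms.
    context_px : crack-filling interpolation neighbourhood (None = global).
    """

    def __init__(
        self,
        alpha: float = 200.0,
        sigma: float = 0.01,
        n_r: int = N_RADIAL,
        n_theta: int = N_THETA,
        eps: float = LOG_EPS,
        context_px: int | None = 4,
    ) -> None:
        self.alpha = alpha
        self.sigma = sigma
        self.n_r = n_r
        self.n_theta = n_theta
        self.eps = eps
        self.context_px = context_px

    def fit(self, X, y=None):  # noqa: D102 - stateless
        self.n_features_out_ = (self.n_r - 1) * int(np.ceil(self.n_theta / 2))
        return self

    def transform(self, X) -> np.ndarray:
        return np.stack(
            [
                image_features(
                    img,
                    alpha=self.alpha,
                    sigma=self.sigma,
                    n_r=self.n_r,
                    n_theta=self.n_theta,
                    eps=self.eps,
                    context_px=self.context_px,
                )
                for img in X
            ]
        )
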