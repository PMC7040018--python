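"""Per-image cleaning chain for dried-droplet photographs.

The chain takes an RGB photograph of a single dried blood droplet and
produces the edge-magnitude image that feeds the polar spectral features:

    red channel -> crack detection -> crack filling -> Fourier-domain
    Gaussian low-pass -> Laplacian magnitude

Cracks in dried blood deposits show up as near-white pixels (high in all
three colour channels) while the deposit itself is red-dominated, so the
crack criterion is simply that blue AND green exceed a threshold ``alpha``.
Detected crack pixels are replaced by piecewise-linear scattered
interpolation of the surrounding intact pixels, which removes the bright
discontinuities without disturbing the underlying deposit texture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

__all__ = [
    "GaussianFilterSpec",
    "red_channel",
    "detect_cracks",
    "fill_cracks",
    "gaussian_lowpass",
    "laplacian_magnitude",
    "preprocess_image",
]

#: default blue/green threshold isolating near-white crack pixels (0-255)
DEFAULT_ALPHA = 200.0


@dataclass(frozen=True)
class GaussianFilterSpec:
    """Width of the frequency-domain Gaussian low-pass.

    ``sigma`` is in cycles per pixel: the filter weight at spatial
    frequency (u, v) is exp(-(u^2 + v^2) / sigma^2), with weight exactly 1
    at DC, so the image mean is preserved.  Note the deliberately
    unconventional denominator (no factor of 2): sigma is the e-folding
    half-width of the transfer function, not a probabilist's standard
    deviation.
    """

    sigma: float = 0.01

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {img.shape}")
    return img


def red_channel(img: np.ndarray) -> np.ndarray:
    """Extract the red channel as a float image.

    The deposit's useful texture is concentrated in the red channel; blue
    and green are retained only for crack detection.
    """
    return _check_rgb(img)[:, :, 0].astype(float)


def detect_cracks(img: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Boolean mask of crack pixels: blue > alpha AND green > alpha."""
    img = _check_rgb(img)
    if not (0 < alpha < 255):
        raise ValueError(f"alpha must lie in (0, 255), got {alpha}")
    green = img[:, :, 1].astype(float)
    blue = img[:, :, 2].astype(float)
    return (blue > alpha) & (green > alpha)


def fill_cracks(
    ch: np.ndarray,
    mask: np.ndarray,
    context_px: int | None = 4,
) -> np.ndarray:
    """Replace masked pixels by linear scattered interpolation of intact ones.

    Masked pixel values are interpolated piecewise-linearly over a Delaunay
    triangulation of un-masked pixel positions; masked pixels that fall
    outside the convex hull of the interpolation points (cracks touching
    the border) are filled nearest-neighbour.

    Parameters
    ----------
    ch : 2-D float array
    mask : boolean array, True where pixels are to be replaced
    context_px : restrict interpolation points to un-masked pixels within
        this many pixels of the mask (cracks are thin, so the local
        neighbourhood determines the interpolant); ``None`` uses every
        un-masked pixel in the image.
    """
    ch = np.asarray(ch, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if ch.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if not mask.any():
        return ch.copy()
    if mask.all():
        raise ValueError("mask covers the whole image; nothing to interpolate from")

    keep = ~mask
    if context_px is not None:
        near = ndimage.binary_dilation(mask, iterations=int(context_px))
        keep = keep & near
    pts = np.argwhere(keep)
    if pts.shape[0] < 3:
        raise ValueError("fewer than 3 un-masked pixels available for interpolation")
    vals = ch[keep]
    query = np.argwhere(mask)

    filled = ch.copy()
    interp = LinearNDInterpolator(pts, vals)
    est = interp(query)
    hole = np.isnan(est)
    if hole.any():  # outside the convex hull: border cracks
        nn = NearestNDInterpolator(pts, vals)
        est[hole] = nn(query[hole])
    filled[mask] = est
    return filled


def gaussian_lowpass(ch: np.ndarray, spec: GaussianFilterSpec | float = 0.01) -> np.ndarray:
    """Low-pass filter by multiplying the 2-D FFT with exp(-(u²+v²)/σ²).

    (u, v) are the discrete spatial frequencies in cycles per pixel.  The
    DC term is weighted exactly 1, so the image mean is preserved, and the
    filter is linear: cascading two passes equals one pass at sigma/sqrt(2).
    """
    if not isinstance(spec, GaussianFilterSpec):
        spec = GaussianFilterSpec(float(spec))
    ch = np.asarray(ch, dtype=float)
    if not np.isfinite(ch).all():
        raise ValueError("input image contains non-finite values")
    ny, nx = ch.shape
    u = np.fft.fftfreq(nx)[None, :]
    v = np.fft.fftfreq(ny)[:, None]
    transfer = np.exp(-(u**2 + v**2) / spec.sigma**2)
    return np.fft.ifft2(np.fft.fft2(ch) * transfer).real


def laplacian_magnitude(ch: np.ndarray) -> np.ndarray:
    """Magnitude of the image Laplacian, sqrt(f_xx² + f_yy²).

    Second derivatives are central finite differences on a replicate-padded
    raster, so output shape equals input shape and the result is
    non-negative everywhere.
    """
    ch = np.asarray(ch, dtype=float)
    if ch.ndim != 2 or min(ch.shape) < 3:
        raise ValueError(f"need a 2-D image of at least 3x3, got shape {ch.shape}")
    padded = np.pad(ch, 1, mode="edge")
    d2y = padded[2:, 1:-1] - 2.0 * ch + padded[:-2, 1:-1]
    d2x = padded[1:-1, 2:] - 2.0 * ch + padded[1:-1, :-2]
    return np.hypot(d2x, d2y)


def preprocess_image(
    img: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    sigma: float = 0.01,
    context_px: int | None = 4,
) -> np.ndarray:
    """Full chain: RGB photo -> Laplacian-magnitude edge image."""
    red = red_channel(img)
    mask = detect_cracks(img, alpha=alpha)
    if mask.any() and not mask.all():
        red = fill_cracks(red, mask, context_px=context_px)
    smooth = gaussian_lowpass(red, GaussianFilterSpec(sigma))
    return laplacian_magnitude(smooth)
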