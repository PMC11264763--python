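"""Color descriptors: per-channel histograms, pixel-based color moments
(PCMD), HSV moments, and the rotation/scale-invariant hybrid descriptor
(RSHD) fusing quantized color shades with binary structure elements.

The color moments use root-moment forms rather than standardized moments:
sigma is the RMS deviation with a 1/N denominator, skewness is the signed
cube root of the third central moment mean, kurtosis the fourth root of the
fourth central moment mean (``moments="standardized"`` switches to the
conventional dimensionless statistics).
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv

from .fixtures_io import ParameterError, RasterImage


def _rgb(image) -> np.ndarray:
    px = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ParameterError("a 3-channel RGB image is required")
    return px


# ---------------------------------------------------------------------------
# histograms and moments
# ---------------------------------------------------------------------------

def color_histogram(image, bins: int = 8) -> dict:
    """Per-channel histograms over ``bins`` uniform bins of [0, 255].

    Counts in each channel sum to the pixel count.
    """
    if bins < 2:
        raise ParameterError("bins must be >= 2")
    px = _rgb(image)
    out = {}
    for c, name in enumerate("RGB"):
        hist, _ = np.histogram(px[:, :, c], bins=bins, range=(0, 256))
        for b, v in enumerate(hist):
            out[f"hist.{name}.bin{b}"] = float(v)
    return out


def _channel_moments(vals: np.ndarray, form: str) -> dict:
    vals = vals.astype(np.float64).ravel()
    n = vals.size
    mu = float(vals.mean())
    dev = vals - mu
    m2 = float(np.mean(dev ** 2))
    m3 = float(np.mean(dev ** 3))
    m4 = float(np.mean(dev ** 4))
    sigma = float(np.sqrt(m2))
    if form == "variant":
        skew = float(np.sign(m3) * np.abs(m3) ** (1.0 / 3.0))
        kurt = float(m4 ** 0.25)
    elif form == "standardized":
        skew = m3 / sigma ** 3 if sigma > 0 else 0.0
        kurt = m4 / sigma ** 4 if sigma > 0 else 0.0
    else:
        raise ParameterError(f"unknown moments form {form!r}")
    return {"mean": mu, "std": sigma, "var": m2, "skew": skew, "kurt": kurt}


def color_moments(image, moments: str = "variant") -> dict:
    """Mean, std, variance, skewness and kurtosis per RGB channel."""
    px = _rgb(image)
    out = {}
    for c, name in enumerate("RGB"):
        for k, v in _channel_moments(px[:, :, c], moments).items():
            out[f"cm.{name}.{k}"] = v
    return out


def hsv_moments(image, moments: str = "variant") -> dict:
    """Moments of the hue (degrees, [0, 360)) and saturation ([0, 1]) channels.

    The value channel is excluded: hue and saturation are the components
    least affected by illumination differences between slides.
    """
    px = _rgb(image)
    hsv = rgb2hsv(px.astype(np.float64) / 255.0)
    chans = {"H": hsv[:, :, 0] * 360.0, "S": hsv[:, :, 1]}
    out = {}
    for name, vals in chans.items():
        for k, v in _channel_moments(vals, moments).items():
            out[f"cm.{name}.{k}"] = v
    return out


# ---------------------------------------------------------------------------
# RSHD
# ---------------------------------------------------------------------------

def quantize_colors(image, shades: int = 64) -> np.ndarray:
    """Quantize RGB into ``shades`` = a**3 single-channel shade indices.

    index = qR*a^2 + qG*a + qB with per-channel bins qC = floor(C*a/256).
    """
    a = round(shades ** (1.0 / 3.0))
    if a ** 3 != shades:
        raise ParameterError("shades must be a perfect cube (e.g. 64)")
    px = _rgb(image).astype(np.int64)
    q = (px * a) // 256
    return (q[:, :, 0] * a * a + q[:, :, 1] * a + q[:, :, 2]).astype(np.int64)


def rshd(image, shades: int = 64) -> np.ndarray:
    """Rotation/scale-invariant hybrid color-texture descriptor.

    For each quantized shade the image is binarized and every 2x2 window is
    classified into one of 5 rotation-invariant structure classes by its
    count of set pixels (0..4; the two-pixel class merges adjacent and
    diagonal pairs, so every class is closed under 90-degree rotations and
    flips).  Counts accumulate into a shades x 5 grid, L1-normalized and
    flattened shade-major.
    """
    smap = quantize_colors(image, shades=shades)
    h, w = smap.shape
    if h < 2 or w < 2:
        raise ParameterError("image must be at least 2x2 for RSHD")
    # 4 cells of every 2x2 window, shape (n_windows, 4)
    cells = np.stack([smap[:-1, :-1], smap[:-1, 1:],
                      smap[1:, :-1], smap[1:, 1:]], axis=-1).reshape(-1, 4)
    n_win = cells.shape[0]
    hist = np.zeros((shades, 5), dtype=np.float64)
    for s in range(shades):
        c = (cells == s).sum(axis=1)
        hist[s] += np.bincount(c, minlength=5)
    return (hist / hist.sum()).ravel()


def rshd_features(image, shades: int = 64) -> dict:
    """RSHD as a named feature block ``rshd.s{shade}.e{class}``."""
    vec = rshd(image, shades=shades)
    return {f"rshd.s{i // 5}.e{i % 5}": float(v) for i, v in enumerate(vec)}
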