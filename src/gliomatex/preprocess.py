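"""Contrast enhancement, tiling and nuclear-density ROI selection.

The enhancement is a two-step scheme: a global log-normalization that
compresses the dynamic range (nuclei on bright eosin backgrounds gain
contrast) followed by contrast-limited adaptive histogram equalization
(CLAHE) on the luminance channel.  Enhanced slides are split into
non-overlapping tiles and the tiles with the highest watershed nucleus count
are kept as regions of interest, mirroring how pathologists focus on the most
cellular fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure
from skimage.color import rgb2hsv, hsv2rgb
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .fixtures_io import ParameterError, RasterImage


@dataclass
class Tile:
    image: RasterImage
    parent_id: str
    grid_position: tuple  # (row, col) in the parent's tile grid
    density_score: float | None = None


@dataclass
class ROISet:
    rois: list
    density_scores: list
    top_n: int


# ---------------------------------------------------------------------------
# enhancement
# ---------------------------------------------------------------------------

def log_normalize(image: RasterImage) -> RasterImage:
    """Global log contrast normalization, per channel.

    output = round(vmax * log(1 + I) / log(1 + I_max)) with I_max the channel
    maximum; an all-zero channel stays all-zero.  Monotone non-decreasing, so
    intensity order is preserved.
    """
    px = image.pixels.astype(np.float64)
    vmax = float(image.max_value)
    chans = px[..., None] if px.ndim == 2 else px
    out = np.empty_like(chans)
    for c in range(chans.shape[2]):
        ch = chans[:, :, c]
        imax = ch.max() if ch.size else 0.0
        if imax <= 0:
            out[:, :, c] = 0.0
        else:
            out[:, :, c] = np.round(vmax * np.log1p(ch) / np.log1p(imax))
    out = out[:, :, 0] if px.ndim == 2 else out
    dtype = np.uint16 if image.bit_depth == 16 else np.uint8
    return RasterImage(out.astype(dtype), bit_depth=image.bit_depth)


def luminance(image: RasterImage) -> np.ndarray:
    """8/16-bit luminance grid (Rec.601 weights for RGB, identity for gray)."""
    px = image.pixels
    if px.ndim == 2:
        return px.copy()
    w = np.array([0.299, 0.587, 0.114])
    return np.round(px.astype(float) @ w).astype(px.dtype)


def apply_clahe(image: RasterImage, grid: tuple = (8, 8),
                clip_limit: float = 0.01) -> RasterImage:
    """CLAHE with an ``grid`` of contextual regions and clip fraction.

    Color images are equalized on the HSV value channel and recombined so hue
    is untouched.  Constant channels are returned unchanged (equalizing a
    single-bin histogram is the identity).
    """
    px = image.pixels
    h, w = px.shape[:2]
    if h < grid[0] or w < grid[1]:
        raise ParameterError("image smaller than the CLAHE grid")
    kernel = (max(1, h // grid[0]), max(1, w // grid[1]))
    vmax = image.max_value

    if px.ndim == 2:
        if px.max() == px.min():
            return RasterImage(px.copy(), bit_depth=image.bit_depth)
        eq = exposure.equalize_adapthist(px, kernel_size=kernel,
                                         clip_limit=clip_limit)
        out = np.round(eq * vmax)
    else:
        hsv = rgb2hsv(px.astype(float) / vmax)
        v = hsv[:, :, 2]
        if v.max() > v.min():
            eqv = exposure.equalize_adapthist(
                np.round(v * vmax).astype(np.uint16 if image.bit_depth == 16 else np.uint8),
                kernel_size=kernel, clip_limit=clip_limit)
            hsv[:, :, 2] = eqv
        out = np.round(hsv2rgb(hsv) * vmax)
    dtype = np.uint16 if image.bit_depth == 16 else np.uint8
    return RasterImage(np.clip(out, 0, vmax).astype(dtype), bit_depth=image.bit_depth)


def enhance(image: RasterImage, grid: tuple = (8, 8),
            clip_limit: float = 0.01) -> RasterImage:
    """Two-step enhancement: log normalization then CLAHE."""
    return apply_clahe(log_normalize(image), grid=grid, clip_limit=clip_limit)


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def tile_image(image: RasterImage, tile_size: int = 512,
               parent_id: str = "img", pad: bool = False) -> list:
    """Split into non-overlapping ``tile_size`` squares, row-major.

    Right/bottom remainder pixels are discarded.  An image smaller than one
    tile is returned whole as a single edge-padded tile when ``pad=True``,
    otherwise it is a parameter error.
    """
    px = image.pixels
    h, w = px.shape[:2]
    if h < tile_size or w < tile_size:
        if not pad:
            raise ParameterError(
                f"image {h}x{w} smaller than tile size {tile_size}")
        py, pxw = max(0, tile_size - h), max(0, tile_size - w)
        padding = [(0, py), (0, pxw)] + ([(0, 0)] if px.ndim == 3 else [])
        padded = np.pad(px, padding, mode="edge")
        return [Tile(RasterImage(padded, bit_depth=image.bit_depth), parent_id, (0, 0))]
    tiles = []
    for r in range(h // tile_size):
        for c in range(w // tile_size):
            sub = px[r * tile_size:(r + 1) * tile_size,
                     c * tile_size:(c + 1) * tile_size]
            tiles.append(Tile(RasterImage(sub.copy(), bit_depth=image.bit_depth),
                              parent_id, (r, c)))
    return tiles


# ---------------------------------------------------------------------------
# nuclear density + ROI selection
# ---------------------------------------------------------------------------

def nuclei_density(tile: Tile, min_distance: int = 5,
                   area_bounds: tuple = (15, 2000)) -> int:
    """Count nuclei in a tile by Otsu + distance-transform watershed.

    Pipeline: luminance -> Otsu threshold keeping dark objects -> Euclidean
    distance transform -> local maxima (``min_distance`` ~ expected nucleus
    radius) as markers -> watershed -> count segments whose area lies in
    ``area_bounds``.  Deterministic for fixed parameters; a constant tile has
    no foreground and scores 0.
    """
    lum = luminance(tile.image).astype(float)
    if lum.max() == lum.min():
        return 0
    thr = threshold_otsu(lum)
    mask = lum < thr  # nuclei are dark on a light background
    if not mask.any():
        return 0
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(dist, min_distance=min_distance, labels=mask,
                           exclude_border=False)
    if len(peaks) == 0:
        return 0
    markers = np.zeros(mask.shape, dtype=int)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=mask)
    lo, hi = area_bounds
    counts = np.bincount(labels.ravel())[1:]  # skip background 0
    return int(np.sum((counts >= lo) & (counts <= hi)))


def select_rois(tiles: list, top_n: int = 5, **density_kwargs) -> ROISet:
    """Keep the ``top_n`` densest tiles; ties break by (row, col) grid order.

    Stable under permutation of the input list.
    """
    if not tiles:
        raise ParameterError("empty tile list")
    scored = []
    for t in tiles:
        score = t.density_score
        if score is None:
            score = nuclei_density(t, **density_kwargs)
            t.density_score = score
        scored.append((t, score))
    # sort by (-density, grid row, grid col): deterministic tie-break
    scored.sort(key=lambda ts: (-ts[1], ts[0].grid_position))
    keep = scored[: min(top_n, len(scored))]
    return ROISet(rois=[t for t, _ in keep],
                  density_scores=[s for _, s in keep],
                  top_n=top_n)
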