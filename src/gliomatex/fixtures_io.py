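"""Image / feature-table I/O, augmentation, and a synthetic labeled-texture generator.

The generator produces procedural H&E-like tiles: a tinted background with
additive Gaussian noise and dark, roughly circular "nuclei" blobs whose
per-class density, radius range and background tint differ.  Classes therefore
separate both in second-order texture statistics (blob density) and in color
moments (tint), so every downstream feature family carries signal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised for malformed image or table files."""


class ParameterError(ValueError):
    """Raised for out-of-range parameters."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RasterImage:
    """Integer intensity grid, top-left origin, row-major, 0-based.

    ``pixels`` is (H, W) for gray or (H, W, 3) for RGB; all intensities lie in
    ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise FormatError("image must be 2-D gray or 3-D color")
        if self.pixels.ndim == 3 and self.pixels.shape[2] not in (1, 3):
            raise FormatError(
                f"unsupported channel count {self.pixels.shape[2]} (need 1 or 3)"
            )
        if self.pixels.ndim == 3 and self.pixels.shape[2] == 1:
            self.pixels = self.pixels[:, :, 0]
        vmax = (1 << self.bit_depth) - 1
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > vmax):
            raise FormatError(f"intensities outside [0, {vmax}]")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class LabeledImageSet:
    """A labeled collection of images plus per-image ground-truth metadata."""

    images: list
    labels: list
    label_codebook: list
    seed: int
    metadata: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.labels):
            raise ParameterError("images and labels length mismatch")
        for lab in self.labels:
            if lab not in self.label_codebook:
                raise ParameterError(f"label {lab!r} outside codebook")


@dataclass
class FeatureTable:
    """Named, ordered feature rows (one per ROI) with optional labels.

    Column names are globally unique and block-prefixed, e.g. ``glcm.contrast``.
    """

    values: np.ndarray
    column_names: list
    labels: list | None = None
    groups: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            self.values = self.values.reshape(len(self.values), -1)
        if self.values.shape[1] != len(self.column_names):
            raise FormatError("column count does not match column_names")
        if len(set(self.column_names)) != len(self.column_names):
            raise FormatError("duplicate column names")
        if self.labels is not None and len(self.labels) != len(self.values):
            raise FormatError("labels length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise FormatError("feature table contains NaN/Inf")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names)
        if self.labels is not None:
            df.insert(0, "label", list(self.labels))
        if self.groups is not None:
            df.insert(0, "group", list(self.groups))
        return df


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def read_image(path) -> RasterImage:
    """Read a PNG or TIFF (8/16-bit, gray or RGB) into a :class:`RasterImage`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim == 3 and arr.shape[2] not in (1, 3):
        raise FormatError(f"{path}: unsupported channel count {arr.shape[2]}")
    bit_depth = 16 if arr.dtype == np.uint16 else 8
    return RasterImage(arr, bit_depth=bit_depth)


def write_image(image: RasterImage, path) -> None:
    """Write an image as PNG or TIFF, preserving 8/16-bit depth."""
    dtype = np.uint16 if image.bit_depth == 16 else np.uint8
    iio.imwrite(Path(path), image.pixels.astype(dtype))


# ---------------------------------------------------------------------------
# synthetic texture generator
# ---------------------------------------------------------------------------

@dataclass
class ClassSpec:
    """Generation recipe for one synthetic tissue class.

    ``n_blobs``     mean number of dark nuclei per image,
    ``radius_range``(lo, hi) nucleus radius in pixels,
    ``tint``        background RGB mean,
    ``noise_scale`` sigma of additive Gaussian pixel noise.
    """

    name: str
    n_blobs: int
    radius_range: tuple = (3.0, 7.0)
    tint: tuple = (200, 160, 200)
    noise_scale: float = 5.0
    blob_color: tuple = (70, 50, 110)


#: Default 4-class ladder: density and tint both vary so texture AND color
#: feature families are informative.
DEFAULT_CLASSES = [
    ClassSpec("grade1", n_blobs=10, tint=(210, 170, 205), radius_range=(3.0, 5.0)),
    ClassSpec("grade2", n_blobs=25, tint=(200, 150, 195), radius_range=(3.0, 6.0)),
    ClassSpec("grade3", n_blobs=45, tint=(185, 135, 190), radius_range=(3.5, 6.5)),
    ClassSpec("grade4", n_blobs=70, tint=(170, 120, 180), radius_range=(4.0, 7.0)),
]


def _render_blobs(size: int, centers, radii, color, canvas) -> None:
    yy, xx = np.mgrid[0:size, 0:size]
    for (cy, cx), r in zip(centers, radii):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        # soft 1-px anti-aliased edge
        alpha = np.clip((r - np.sqrt(d2)) + 0.5, 0.0, 1.0)
        for c in range(3):
            canvas[:, :, c] = alpha * color[c] + (1 - alpha) * canvas[:, :, c]


def _sample_centers(rng, size, n, radii, min_sep_factor=1.1, max_tries=2000):
    """Rejection-sample blob centers so disks rarely touch (watershed-friendly)."""
    centers = []
    placed_r = []
    tries = 0
    i = 0
    while i < n and tries < max_tries:
        tries += 1
        r = radii[i]
        cy = rng.uniform(r + 1, size - r - 1)
        cx = rng.uniform(r + 1, size - r - 1)
        ok = all(
            (cy - py) ** 2 + (cx - px) ** 2 >= (min_sep_factor * (r + pr)) ** 2
            for (py, px), pr in zip(centers, placed_r)
        )
        if ok:
            centers.append((cy, cx))
            placed_r.append(r)
            i += 1
    return centers


def generate_texture_dataset(
    n_per_class: int,
    classes: Sequence[ClassSpec] | None = None,
    image_size: int = 128,
    seed: int = 0,
) -> LabeledImageSet:
    """Generate a deterministic labeled set of synthetic 8-bit RGB textures.

    Each image records its true nucleus count in ``metadata`` so segmentation
    accuracy can be scored against ground truth.
    """
    if image_size < 32:
        raise ParameterError("image_size must be >= 32")
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    classes = list(DEFAULT_CLASSES) if classes is None else list(classes)

    rng = np.random.default_rng(seed)
    images, labels, metadata = [], [], []
    for spec in classes:
        for _ in range(n_per_class):
            canvas = np.empty((image_size, image_size, 3), float)
            for c in range(3):
                canvas[:, :, c] = spec.tint[c]
            canvas += rng.normal(0.0, spec.noise_scale, canvas.shape)
            lo, hi = spec.radius_range
            radii = rng.uniform(lo, hi, spec.n_blobs)
            centers = _sample_centers(rng, image_size, spec.n_blobs, radii)
            _render_blobs(image_size, centers, radii[: len(centers)],
                          spec.blob_color, canvas)
            arr = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
            images.append(RasterImage(arr))
            labels.append(spec.name)
            metadata.append({"n_blobs": len(centers),
                             "centers": centers,
                             "radii": list(radii[: len(centers)])})
    return LabeledImageSet(
        images=images,
        labels=labels,
        label_codebook=[s.name for s in classes],
        seed=seed,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

_SHIFT_RE = re.compile(r"^shift:(-?\d+),(-?\d+)$")
_ZOOM_RE = re.compile(r"^zoom:([\d.]+)$")


def augment_image(image: RasterImage, op: str, seed: int = 0) -> RasterImage:
    """Apply one augmentation op; output keeps the input's shape.

    ``op`` is one of ``"rot90:K"`` (K quarter turns, lossless), ``"flip:h"`` /
    ``"flip:v"``, ``"shift:DY,DX"`` (edge replication) or ``"zoom:F"``
    (bilinear, F in [0.5, 2], center crop/edge pad back to the input size).
    Right-angle rotations and flips are exact; non-right-angle rotation is
    unsupported.
    """
    from scipy import ndimage as ndi

    px = image.pixels
    if op.startswith("rot90:"):
        k = int(op.split(":")[1])
        out = np.rot90(px, k=k, axes=(0, 1))
    elif op in ("flip:h", "flip:v"):
        axis = 1 if op == "flip:h" else 0
        out = np.flip(px, axis=axis)
    elif m := _SHIFT_RE.match(op):
        dy, dx = int(m.group(1)), int(m.group(2))
        h, w = px.shape[:2]
        if abs(dy) >= h or abs(dx) >= w:
            raise ParameterError("shift magnitude must be smaller than the image")
        pad = [(max(dy, 0), max(-dy, 0)), (max(dx, 0), max(-dx, 0))]
        if px.ndim == 3:
            pad.append((0, 0))
        padded = np.pad(px, pad, mode="edge")
        out = padded[max(-dy, 0):max(-dy, 0) + h, max(-dx, 0):max(-dx, 0) + w]
    elif m := _ZOOM_RE.match(op):
        f = float(m.group(1))
        if not 0.5 <= f <= 2.0:
            raise ParameterError("zoom factor must lie in [0.5, 2]")
        h, w = px.shape[:2]
        zoom = (f, f, 1) if px.ndim == 3 else (f, f)
        z = ndi.zoom(px.astype(float), zoom, order=1, mode="nearest")
        zh, zw = z.shape[:2]
        if zh >= h:  # center crop
            y0, x0 = (zh - h) // 2, (zw - w) // 2
            z = z[y0:y0 + h, x0:x0 + w]
        else:  # edge pad
            py0 = (h - zh) // 2
            px0 = (w - zw) // 2
            pad = [(py0, h - zh - py0), (px0, w - zw - px0)]
            if px.ndim == 3:
                pad.append((0, 0))
            z = np.pad(z, pad, mode="edge")
        out = np.clip(np.round(z), 0, image.max_value)
    elif op.startswith("rot:"):
        raise ParameterError("only right-angle rotations are supported (rot90:K)")
    else:
        raise ParameterError(f"unknown augmentation op {op!r}")
    return RasterImage(out.astype(px.dtype), bit_depth=image.bit_depth)


def augment_set(dataset: LabeledImageSet, ops: Sequence[str], seed: int = 0) -> LabeledImageSet:
    """Expand a labeled set with augmented copies (original images kept first)."""
    images = list(dataset.images)
    labels = list(dataset.labels)
    metadata = list(dataset.metadata) or [{} for _ in dataset.images]
    for op in ops:
        for img, lab, meta in zip(dataset.images, dataset.labels, dataset.metadata or []):
            images.append(augment_image(img, op, seed=seed))
            labels.append(lab)
            metadata.append(dict(meta))
    return LabeledImageSet(images, labels, list(dataset.label_codebook),
                           dataset.seed, metadata)


# ---------------------------------------------------------------------------
# feature-table I/O
# ---------------------------------------------------------------------------

def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as CSV with a header row (lossless round trip)."""
    table.to_frame().to_csv(Path(path), index=False)


def read_feature_table(path) -> FeatureTable:
    """Read a CSV feature table written by :func:`write_feature_table`."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        msg = str(exc)
        m = re.search(r"line (\d+)", msg)
        row = f" (row {m.group(1)})" if m else ""
        raise FormatError(f"ragged or malformed CSV {path}{row}: {msg}") from exc
    labels = None
    groups = None
    if "label" in df.columns:
        labels = df.pop("label").tolist()
    if "group" in df.columns:
        groups = df.pop("group").tolist()
    return FeatureTable(df.to_numpy(dtype=float), list(df.columns),
                        labels=labels, groups=groups)
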