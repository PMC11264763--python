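"""Second-order texture descriptors for histopathology tiles.

Families implemented here:

* GLCM — gray-level co-occurrence statistics (contrast, homogeneity,
  correlation, energy, dissimilarity, entropy) over the four standard
  offsets 0/45/90/135 degrees at distance 1;
* GLRLM — gray-level run-length statistics (SRE, LRE, GLN, RLN), with both
  the variant formulas used by this pipeline (per-term ``1+(i+j)`` /
  ``1+|i-j|`` denominators, central-moment non-uniformities) and the
  classical Galloway definitions behind a switch;
* LBP — rotation-invariant uniform (riu2) local binary patterns at three
  (P, R) resolutions, plus heterogeneity-weighted LBP histograms where each
  pixel votes with its local variance V or local dissimilarity 1-H;
* LBGLCM — GLCM statistics of the LBP-coded image, and its multi-scale
  extension over a Gaussian image pyramid.

Conventions: gray levels are quantized uniformly; the GLCM homogeneity
denominator defaults to the variant ``1+(i+j)^2`` form with 0-based levels
(``homogeneity="standard"`` restores ``1+(i-j)^2``); the LBP sign function has
``s(0)=1`` and bit p sits at angle 2*pi*p/P counter-clockwise from the
positive x axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import local_binary_pattern

from .fixtures_io import ParameterError, RasterImage

#: (dr, dc) offsets for 0, 45, 90, 135 degrees at distance 1.
GLCM_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

#: Default multi-resolution LBP operating points.
DEFAULT_LBP_SET = ((8, 1), (16, 2), (24, 3))


def _as_grid(image) -> np.ndarray:
    if isinstance(image, RasterImage):
        if image.n_channels != 1:
            raise ParameterError("texture operators need a gray image")
        return image.pixels
    return np.asarray(image)


def lbp_binary_to_decimal(bits: str) -> int:
    """Decimal LBP code of a binary neighbor string (MSB first).

    Converting the clockwise comparison string ``"11001001"`` yields 201.
    """
    if not bits or set(bits) - {"0", "1"}:
        raise ParameterError(f"not a binary string: {bits!r}")
    return int(bits, 2)


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def quantize_gray(image, levels: int, bit_depth: int = 8) -> np.ndarray:
    """Uniformly bin ``[0, 2**bit_depth - 1]`` into ``levels`` gray levels.

    value v maps to ``floor(v * levels / 2**bit_depth)`` clipped to levels-1.
    """
    if levels < 2:
        raise ParameterError("levels must be >= 2")
    grid = _as_grid(image).astype(np.int64)
    q = (grid * levels) >> bit_depth if (levels & (levels - 1)) == 0 else \
        (grid * levels) // (1 << bit_depth)
    return np.minimum(q, levels - 1).astype(np.int64)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

@dataclass
class CooccurrenceMatrix:
    """Normalized co-occurrence probabilities p(i, j) for one offset."""

    p: np.ndarray
    levels: int
    angle: int
    symmetric: bool = True

    @property
    def mu_x(self) -> float:
        i = np.arange(self.levels)
        return float(np.sum(i * self.p.sum(axis=1)))

    @property
    def mu_y(self) -> float:
        j = np.arange(self.levels)
        return float(np.sum(j * self.p.sum(axis=0)))

    @property
    def sigma_x(self) -> float:
        i = np.arange(self.levels)
        return float(np.sqrt(np.sum((i - self.mu_x) ** 2 * self.p.sum(axis=1))))

    @property
    def sigma_y(self) -> float:
        j = np.arange(self.levels)
        return float(np.sqrt(np.sum((j - self.mu_y) ** 2 * self.p.sum(axis=0))))


def compute_glcm(gray, levels: int, angles=(0, 45, 90, 135),
                 symmetric: bool = True) -> list:
    """Co-occurrence matrices at distance 1 for the requested angles.

    Pairs (pixel, pixel+offset) inside the grid are counted; in symmetric
    mode the transpose is added before normalizing to sum 1.
    """
    q = _as_grid(gray)
    if q.max() >= levels:
        raise ParameterError("grid values must be < levels")
    h, w = q.shape
    out = []
    for ang in angles:
        dr, dc = GLCM_OFFSETS[ang]
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r1 <= r0 or c1 <= c0:
            raise ParameterError(f"image too small for offset at {ang} degrees")
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        counts = np.zeros((levels, levels), dtype=np.float64)
        np.add.at(counts, (a, b), 1.0)
        if symmetric:
            counts = counts + counts.T
        total = counts.sum()
        out.append(CooccurrenceMatrix(counts / total, levels, ang, symmetric))
    return out


GLCM_FEATURE_NAMES = ("contrast", "homogeneity", "correlation", "energy",
                      "dissimilarity", "entropy")


def glcm_features(M: CooccurrenceMatrix, homogeneity: str = "variant") -> dict:
    """The six co-occurrence statistics of one matrix.

    contrast   = sum |i-j|^2 p(i,j)
    homogeneity= sum p(i,j) / (1 + (i+j)^2)      (variant; "standard" uses i-j)
    correlation= sum p(i,j) (i-mu_x)(j-mu_y) / (sigma_x sigma_y), 0 if degenerate
    energy     = sum p(i,j)^2
    dissimilar = sum |i-j| p(i,j)
    entropy    = -sum p log2 p over nonzero entries (bits)
    """
    p = M.p
    n = M.levels
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    diff = i - j
    contrast = float(np.sum(diff ** 2 * p))
    if homogeneity == "variant":
        homog = float(np.sum(p / (1.0 + (i + j) ** 2)))
    elif homogeneity == "standard":
        homog = float(np.sum(p / (1.0 + diff ** 2)))
    else:
        raise ParameterError(f"unknown homogeneity form {homogeneity!r}")
    sx, sy = M.sigma_x, M.sigma_y
    if sx <= 1e-12 or sy <= 1e-12:
        corr = 0.0
    else:
        corr = float(np.sum(p * (i - M.mu_x) * (j - M.mu_y)) / (sx * sy))
    energy = float(np.sum(p ** 2))
    dissim = float(np.sum(np.abs(diff) * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return {"contrast": contrast, "homogeneity": homog, "correlation": corr,
            "energy": energy, "dissimilarity": dissim, "entropy": entropy}


def glcm_feature_vector(gray, levels: int = 64, homogeneity: str = "variant",
                        average: bool = True, bit_depth: int = 8) -> dict:
    """Direction-averaged GLCM features of a (raw or quantized) gray grid."""
    grid = _as_grid(gray)
    q = quantize_gray(grid, levels, bit_depth=bit_depth) if grid.max() >= levels \
        else grid.astype(np.int64)
    mats = compute_glcm(q, levels)
    feats = [glcm_features(m, homogeneity=homogeneity) for m in mats]
    if average:
        return {k: float(np.mean([f[k] for f in feats])) for k in GLCM_FEATURE_NAMES}
    return {f"{k}.d{m.angle}": f[k]
            for m, f in zip(mats, feats) for k in GLCM_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

@dataclass
class RunLengthMatrix:
    """Run counts by (gray level, run length) for one scan direction.

    ``counts[i, j-1]`` is the number of maximal runs of 1-based level ``i+1``
    and length ``j``.  ``mean_gray`` is the image's mean gray level on the
    same 1-based scale; ``mean_run_length`` is pixels scanned / total runs.
    """

    counts: np.ndarray
    levels: int
    angle: int
    n_pixels: int
    mean_gray: float

    @property
    def p(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts

    @property
    def n_runs(self) -> float:
        return float(self.counts.sum())

    @property
    def mean_run_length(self) -> float:
        j = np.arange(1, self.counts.shape[1] + 1)
        return float(np.sum(self.counts * j) / self.counts.sum())


def _run_lengths(line: np.ndarray):
    """(values, lengths) arrays of maximal constant runs in a 1-D array."""
    if line.size == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [line.size]))
    return line[starts], ends - starts


def _scan_lines(q: np.ndarray, angle: int):
    h, w = q.shape
    if angle == 0:
        yield from q
    elif angle == 90:
        yield from q.T
    elif angle == 45:
        f = np.fliplr(q)
        for k in range(-(h - 1), w):
            yield np.diagonal(f, offset=k)
    elif angle == 135:
        for k in range(-(h - 1), w):
            yield np.diagonal(q, offset=k)
    else:
        raise ParameterError(f"unsupported GLRLM angle {angle}")


def compute_glrlm(gray, levels: int, angles=(0, 45, 90, 135)) -> list:
    """Run-length matrices for each angle (maximal same-level runs)."""
    q = _as_grid(gray).astype(np.int64)
    if q.max() >= levels:
        raise ParameterError("grid values must be < levels")
    lmax = max(q.shape)
    mean_gray = float(q.mean()) + 1.0  # 1-based level scale
    out = []
    for ang in angles:
        counts = np.zeros((levels, lmax), dtype=np.float64)
        n_px = 0
        for line in _scan_lines(q, ang):
            n_px += line.size
            vals, lens = _run_lengths(np.ascontiguousarray(line))
            np.add.at(counts, (vals, lens - 1), 1.0)
        out.append(RunLengthMatrix(counts, levels, ang, n_px, mean_gray))
    return out


GLRLM_FEATURE_NAMES = ("sre", "lre", "gln", "rln")


def glrlm_features(M: RunLengthMatrix, mu_r: float | None = None,
                   formulas: str = "variant") -> dict:
    """SRE, LRE, GLN, RLN of one run-length matrix.

    The default variant forms use per-term denominators and central moments:
    SRE = sum p/(1+(i+j)), LRE = sum p/(1+|i-j|), GLN = sum p (i-mu_g)^2 with
    mu_g the image's mean gray level, RLN = sum p (j-mu_r)^2 with mu_r the
    mean run length (pass the all-directions average for the multi-direction
    descriptor).  ``formulas="standard"`` switches to the classical Galloway
    definitions (SRE = sum p/j^2, LRE = sum p j^2, GLN/RLN marginal-square
    sums over the normalized matrix).
    """
    if M.counts.sum() == 0:
        raise ParameterError("empty run-length matrix")
    p = M.p
    i = np.arange(1, M.levels + 1)[:, None].astype(float)
    j = np.arange(1, p.shape[1] + 1)[None, :].astype(float)
    if formulas == "variant":
        sre = float(np.sum(p / (1.0 + (i + j))))
        lre = float(np.sum(p / (1.0 + np.abs(i - j))))
        gln = float(np.sum(p * (i - M.mean_gray) ** 2))
        mr = M.mean_run_length if mu_r is None else mu_r
        rln = float(np.sum(p * (j - mr) ** 2))
    elif formulas == "standard":
        sre = float(np.sum(p / j ** 2))
        lre = float(np.sum(p * j ** 2))
        gln = float(np.sum(p.sum(axis=1) ** 2) / (p.sum() if p.sum() else 1.0))
        rln = float(np.sum(p.sum(axis=0) ** 2) / (p.sum() if p.sum() else 1.0))
    else:
        raise ParameterError(f"unknown GLRLM formulas {formulas!r}")
    return {"sre": sre, "lre": lre, "gln": gln, "rln": rln}


def glrlm_feature_vector(gray, levels: int = 64, formulas: str = "variant",
                         bit_depth: int = 8) -> dict:
    """Direction-averaged GLRLM features; mu_r pooled over all directions."""
    grid = _as_grid(gray)
    q = quantize_gray(grid, levels, bit_depth=bit_depth) if grid.max() >= levels \
        else grid.astype(np.int64)
    mats = compute_glrlm(q, levels)
    total_px = sum(m.n_pixels for m in mats)
    total_runs = sum(m.n_runs for m in mats)
    mu_r = total_px / total_runs
    feats = [glrlm_features(m, mu_r=mu_r, formulas=formulas) for m in mats]
    return {k: float(np.mean([f[k] for f in feats])) for k in GLRLM_FEATURE_NAMES}


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

@dataclass
class LBPMap:
    """Per-pixel LBP codes (border of width ceil(R) excluded)."""

    codes: np.ndarray
    P: int
    R: float
    variant: str  # "basic" or "riu2"

    @property
    def n_bins(self) -> int:
        return (1 << self.P) if self.variant == "basic" else self.P + 2


def lbp_map(gray, P: int = 8, R: float = 1, variant: str = "riu2") -> LBPMap:
    """Circular LBP codes; ``s(x)=1`` iff x >= 0; bilinear neighbor sampling.

    Bit p corresponds to the neighbor at angle 2*pi*p/P counter-clockwise
    from the positive x axis.  riu2 maps uniform rotation classes to [0, P]
    and non-uniform patterns to P+1.
    """
    grid = _as_grid(gray)
    if not np.issubdtype(grid.dtype, np.integer):
        grid = np.round(grid).astype(np.int64)
    b = int(np.ceil(R))
    if grid.shape[0] < 2 * b + 1 or grid.shape[1] < 2 * b + 1:
        raise ParameterError("image smaller than the LBP neighborhood")
    method = "default" if variant == "basic" else "uniform"
    if variant not in ("basic", "riu2"):
        raise ParameterError(f"unknown LBP variant {variant!r}")
    codes = local_binary_pattern(grid, P, R, method=method)
    codes = codes[b:grid.shape[0] - b, b:grid.shape[1] - b]
    return LBPMap(codes.astype(np.int64), P, R, variant)


def lbp_histogram_features(gray, pr_set=DEFAULT_LBP_SET) -> dict:
    """Concatenated normalized riu2 histograms at each (P, R) in ``pr_set``."""
    out = {}
    for P, R in pr_set:
        m = lbp_map(gray, P=P, R=R, variant="riu2")
        hist = np.bincount(m.codes.ravel(), minlength=m.n_bins).astype(float)
        hist /= hist.sum()
        for b, v in enumerate(hist):
            out[f"p{P}r{R}.bin{b}"] = float(v)
    return out


# ---------------------------------------------------------------------------
# heterogeneity
# ---------------------------------------------------------------------------

@dataclass
class HeterogeneityMaps:
    """Per-pixel local variance V and local homogeneity H.

    V >= 0 everywhere; H <= 1 with H = 1 exactly on constant neighborhoods.
    """

    variance_map: np.ndarray
    homogeneity_map: np.ndarray
    P: int
    R: float


def _circular_samples(grid: np.ndarray, P: int, R: float) -> np.ndarray:
    """(P, H', W') bilinear samples on the LBP circle around interior pixels."""
    b = int(np.ceil(R))
    h, w = grid.shape
    yy, xx = np.mgrid[b:h - b, b:w - b].astype(float)
    samples = np.empty((P, h - 2 * b, w - 2 * b))
    for p in range(P):
        theta = 2.0 * np.pi * p / P
        ry = -R * np.sin(theta)
        rx = R * np.cos(theta)
        samples[p] = ndi.map_coordinates(grid, [yy + ry, xx + rx], order=1,
                                         mode="nearest")
    return samples


def heterogeneity_maps(gray, P: int = 8, R: float = 1) -> HeterogeneityMaps:
    """Local variance V = (1/P) sum (g_i - mu)^2 and homogeneity
    H = 1 - (1/L) sqrt(sum (w - m)^2) with m the neighborhood median and
    L = P the neighborhood size, over the same circular neighbors as the LBP.
    """
    grid = _as_grid(gray).astype(np.float64)
    b = int(np.ceil(R))
    if grid.shape[0] < 2 * b + 1 or grid.shape[1] < 2 * b + 1:
        raise ParameterError("image smaller than the neighborhood")
    s = _circular_samples(grid, P, R)
    mu = s.mean(axis=0)
    V = np.mean((s - mu) ** 2, axis=0)
    m = np.median(s, axis=0)
    dev = np.sqrt(np.sum((s - m) ** 2, axis=0))
    H = 1.0 - dev / P
    # neighborhoods constant to within bilinear rounding report exactly
    # V = 0, H = 1 so the degenerate contracts hold bit-for-bit
    V[V < 1e-12] = 0.0
    H[dev < 1e-9] = 1.0
    return HeterogeneityMaps(V, np.minimum(H, 1.0), P, R)


def heterogeneity_weighted_lbp(lbp: LBPMap, het: HeterogeneityMaps,
                               mode: str = "variance") -> np.ndarray:
    """LBP histogram where each pixel votes with weight V or 1-H.

    Normalized to sum 1 when total weight > 0, all zeros otherwise (a
    constant image has zero heterogeneity everywhere).
    """
    if mode == "variance":
        w = het.variance_map
    elif mode == "dissimilarity":
        w = 1.0 - het.homogeneity_map
    else:
        raise ParameterError(f"unknown weighting mode {mode!r}")
    if w.shape != lbp.codes.shape:
        raise ParameterError("LBP map and heterogeneity map shapes differ")
    hist = np.bincount(lbp.codes.ravel(), weights=w.ravel(),
                       minlength=lbp.n_bins).astype(float)
    total = hist.sum()
    return hist / total if total > 0 else hist


def weighted_lbp_features(gray, pr_set=DEFAULT_LBP_SET) -> dict:
    """Variance- and dissimilarity-weighted riu2 histograms at each (P, R)."""
    out = {}
    for P, R in pr_set:
        m = lbp_map(gray, P=P, R=R, variant="riu2")
        het = heterogeneity_maps(gray, P=P, R=R)
        for mode, tag in (("variance", "v"), ("dissimilarity", "d")):
            hist = heterogeneity_weighted_lbp(m, het, mode=mode)
            for b, v in enumerate(hist):
                out[f"w{tag}.p{P}r{R}.bin{b}"] = float(v)
    return out


# ---------------------------------------------------------------------------
# LBGLCM and the multi-scale pyramid extension
# ---------------------------------------------------------------------------

def lbglcm_features(gray, P: int = 8, R: float = 1, levels: int = 64,
                    homogeneity: str = "variant") -> dict:
    """GLCM statistics of the basic-LBP-coded image.

    The 2**P LBP codes are re-quantized to ``levels`` gray levels before the
    co-occurrence step.
    """
    m = lbp_map(gray, P=P, R=R, variant="basic")
    q = quantize_gray(m.codes, levels, bit_depth=P)
    mats = compute_glcm(q, levels)
    feats = [glcm_features(mm, homogeneity=homogeneity) for mm in mats]
    return {k: float(np.mean([f[k] for f in feats])) for k in GLCM_FEATURE_NAMES}


def image_pyramid(gray, n_levels: int) -> list:
    """Gaussian pyramid: level 0 is the input; each next level is smoothed
    (sigma = 1) and factor-2 decimated with floor size semantics."""
    grid = _as_grid(gray)
    if n_levels < 1:
        raise ParameterError("n_levels must be >= 1")
    need = (1 << (n_levels - 1)) * 16
    if min(grid.shape) < need:
        raise ParameterError(
            f"image min side {min(grid.shape)} < {need} required for "
            f"{n_levels} pyramid levels")
    levels = [grid.copy()]
    cur = grid.astype(np.float64)
    for _ in range(n_levels - 1):
        sm = ndi.gaussian_filter(cur, sigma=1.0, mode="nearest")
        h, w = sm.shape
        cur = sm[: 2 * (h // 2):2, : 2 * (w // 2):2]
        levels.append(np.clip(np.round(cur), 0, 255).astype(grid.dtype))
    return levels


#: GLCM quantization per pyramid level: finer at full resolution.
PYRAMID_GLCM_LEVELS = (128, 64, 64)


def multiscale_lbglcm(gray, n_levels: int = 3, P: int = 8, R: float = 1,
                      glcm_levels=PYRAMID_GLCM_LEVELS,
                      homogeneity: str = "variant") -> dict:
    """LBGLCM features at every pyramid scale, concatenated level 0 upward.

    Values are raw; per-block min-max normalization against training-set
    statistics happens in the fused-feature scaler so no test-set statistics
    leak into the descriptor.
    """
    out = {}
    for lvl, g in enumerate(image_pyramid(gray, n_levels)):
        nlev = glcm_levels[min(lvl, len(glcm_levels) - 1)]
        feats = lbglcm_features(g, P=P, R=R, levels=nlev, homogeneity=homogeneity)
        for k, v in feats.items():
            out[f"l{lvl}.{k}"] = v
    return out
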