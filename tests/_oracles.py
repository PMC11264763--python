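"""Independent brute-force oracles used by the test suite.

Everything here is written as naive explicit loops, deliberately sharing no
code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_oracle(q, levels, angle, symmetric=True):
    """Pair-enumeration co-occurrence matrix."""
    h, w = q.shape
    dr, dc = OFFSETS[angle]
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c], q[r2, c2]] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def glcm_features_oracle(p, homogeneity="variant"):
    n = p.shape[0]
    mu_x = sum(i * p[i, j] for i in range(n) for j in range(n))
    mu_y = sum(j * p[i, j] for i in range(n) for j in range(n))
    sx = math.sqrt(sum((i - mu_x) ** 2 * p[i, j]
                       for i in range(n) for j in range(n)))
    sy = math.sqrt(sum((j - mu_y) ** 2 * p[i, j]
                       for i in range(n) for j in range(n)))
    contrast = sum(abs(i - j) ** 2 * p[i, j]
                   for i in range(n) for j in range(n))
    if homogeneity == "variant":
        hom = sum(p[i, j] / (1 + (i + j) ** 2)
                  for i in range(n) for j in range(n))
    else:
        hom = sum(p[i, j] / (1 + (i - j) ** 2)
                  for i in range(n) for j in range(n))
    if sx < 1e-12 or sy < 1e-12:
        corr = 0.0
    else:
        corr = sum(p[i, j] * (i - mu_x) * (j - mu_y)
                   for i in range(n) for j in range(n)) / (sx * sy)
    energy = sum(p[i, j] ** 2 for i in range(n) for j in range(n))
    dis = sum(abs(i - j) * p[i, j] for i in range(n) for j in range(n))
    ent = -sum(p[i, j] * math.log2(p[i, j])
               for i in range(n) for j in range(n) if p[i, j] > 0)
    return {"contrast": contrast, "homogeneity": hom, "correlation": corr,
            "energy": energy, "dissimilarity": dis, "entropy": ent}


def runs_oracle(q, levels, angle):
    """Explicit scan-line run enumeration -> (counts matrix, n_pixels)."""
    h, w = q.shape
    lines = []
    if angle == 0:
        lines = [q[r, :].tolist() for r in range(h)]
    elif angle == 90:
        lines = [q[:, c].tolist() for c in range(w)]
    elif angle == 45:
        for s in range(h + w - 1):  # r + c = s, traversed upward-right
            line = [q[r, s - r] for r in range(h - 1, -1, -1)
                    if 0 <= s - r < w]
            lines.append(line)
    elif angle == 135:
        for d in range(-(h - 1), w):  # c - r = d
            line = [q[r, r + d] for r in range(h) if 0 <= r + d < w]
            lines.append(line)
    counts = np.zeros((levels, max(h, w)))
    n_px = 0
    for line in lines:
        n_px += len(line)
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            counts[line[i], j - i - 1] += 1
            i = j
    return counts, n_px


def glrlm_features_oracle(counts, mean_gray, mu_r=None):
    """Per-term variant formulas, 1-based indices, explicit loops."""
    p = counts / counts.sum()
    ng, lmax = p.shape
    total_j = sum(p[i, j] * (j + 1) for i in range(ng) for j in range(lmax))
    mr = total_j if mu_r is None else mu_r
    sre = sum(p[i, j] / (1 + (i + 1) + (j + 1))
              for i in range(ng) for j in range(lmax))
    lre = sum(p[i, j] / (1 + abs((i + 1) - (j + 1)))
              for i in range(ng) for j in range(lmax))
    gln = sum(p[i, j] * ((i + 1) - mean_gray) ** 2
              for i in range(ng) for j in range(lmax))
    rln = sum(p[i, j] * ((j + 1) - mr) ** 2
              for i in range(ng) for j in range(lmax))
    return {"sre": sre, "lre": lre, "gln": gln, "rln": rln}


def lbp_oracle(gray, P, R):
    """Naive per-pixel circular LBP, bilinear sampling, s(0)=1 -> basic codes.

    Also returns the per-pixel minimum |sample - center| over neighbors whose
    sampling involved interpolation, so callers can exclude pixels where the
    s() threshold is a floating-point coin toss.
    """
    g = np.asarray(gray, dtype=float)
    h, w = g.shape
    b = int(np.ceil(R))
    codes = np.zeros((h - 2 * b, w - 2 * b), dtype=int)
    tie_margin = np.full((h - 2 * b, w - 2 * b), np.inf)
    for r in range(b, h - b):
        for c in range(b, w - b):
            code = 0
            for p in range(P):
                theta = 2 * math.pi * p / P
                ry = r - R * math.sin(theta)
                cx = c + R * math.cos(theta)
                y0, x0 = int(math.floor(ry)), int(math.floor(cx))
                fy, fx = ry - y0, cx - x0
                y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
                val = (g[y0, x0] * (1 - fy) * (1 - fx)
                       + g[y0, x1] * (1 - fy) * fx
                       + g[y1, x0] * fy * (1 - fx)
                       + g[y1, x1] * fy * fx)
                if val >= g[r, c]:
                    code |= 1 << p
                interpolated = abs(fy) > 1e-9 or abs(fx) > 1e-9
                if interpolated:
                    tie_margin[r - b, c - b] = min(tie_margin[r - b, c - b],
                                                   abs(val - g[r, c]))
            codes[r - b, c - b] = code
    return codes, tie_margin


def riu2_oracle(code, P):
    """Map a basic code to its rotation-invariant uniform class."""
    bits = [(code >> p) & 1 for p in range(P)]
    transitions = sum(bits[p] != bits[(p + 1) % P] for p in range(P))
    return sum(bits) if transitions <= 2 else P + 1


def moments_oracle(vals):
    """Per-pixel loop root-moment statistics."""
    vals = [float(v) for v in np.asarray(vals).ravel()]
    n = len(vals)
    mu = sum(vals) / n
    m2 = sum((v - mu) ** 2 for v in vals) / n
    m3 = sum((v - mu) ** 3 for v in vals) / n
    m4 = sum((v - mu) ** 4 for v in vals) / n
    skew = math.copysign(abs(m3) ** (1 / 3), m3) if m3 else 0.0
    return {"mean": mu, "std": math.sqrt(m2), "var": m2,
            "skew": skew, "kurt": m4 ** 0.25}


def mode_oracle(votes):
    """Mode with 3-way ties resolved to the first vote."""
    counts = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    if best == 1:
        return votes[0]
    return [v for v, c in counts.items() if c == best][0]


def auc_pairs_oracle(scores, labels):
    """Mann-Whitney pair counting with 0.5 credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))
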