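"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is written as literal, loop-based restatements of the
rules (or uses a different geometry library), deliberately sharing no
code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import MultiPoint, Point


# ---------------------------------------------------------------------
# Y-threshold rule chain, bin by bin
# ---------------------------------------------------------------------

def smooth_oracle(hist, window=25):
    """Centered moving average, symmetric padding, explicit loops."""
    h = [int(round(v)) for v in hist]
    pad = window // 2
    padded = h[:pad][::-1] + h + h[-pad:][::-1]
    out = []
    for i in range(len(h)):
        out.append(sum(padded[i:i + window]) / window)
    return out


def y_threshold_oracle(hist, window=25, dark_low=10, dark_high=156,
                       dark_thr=10, min_sep=30, valley_frac=0.10):
    """Returns (status, threshold) per the stated rules, scanned bin by bin."""
    sm = smooth_oracle(hist, window)
    n = len(sm)
    if sum(sm[:dark_low]) > sum(sm[n - dark_high:]):
        return "dark", dark_thr

    # strict local maxima; plateaus keep their leftmost bin
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sm[j + 1] == sm[i]:
            j += 1
        if i > 0 and j < n - 1 and sm[i - 1] < sm[i] and sm[j + 1] < sm[i]:
            peaks.append(i)
        i = j + 1

    # merge peaks closer than min_sep, keeping the larger (ties: lower index)
    merged = True
    while merged:
        merged = False
        for k in range(len(peaks) - 1):
            if peaks[k + 1] - peaks[k] < min_sep:
                if sm[peaks[k + 1]] > sm[peaks[k]]:
                    peaks.pop(k)
                else:
                    peaks.pop(k + 1)
                merged = True
                break

    if len(peaks) < 2:
        return "discarded", None
    p1, p2 = peaks[0], peaks[1]
    cut = valley_frac * sm[p2]
    best = None
    for j in range(p1 + 1, p2):          # closest-to-p2 candidate wins
        if sm[j] < cut:
            best = j
    if best is not None:
        return "valid", best
    best, best_val = p1 + 1, sm[p1 + 1]
    for j in range(p1 + 1, p2):
        if sm[j] < best_val:
            best, best_val = j, sm[j]
    return "valid", best


# ---------------------------------------------------------------------
# solidity: convex hull via shapely on the lattice convention
# (pixel coordinates augmented by half-pixel diamond offsets)
# ---------------------------------------------------------------------

def solidity_oracle(coords, shape) -> float:
    pts = []
    for r, c in coords:
        pts += [(r + 0.5, c), (r - 0.5, c), (r, c + 0.5), (r, c - 0.5)]
    hull = MultiPoint(pts).convex_hull.buffer(1e-9)
    hull_pixels = sum(hull.covers(Point(r, c))
                      for r in range(shape[0]) for c in range(shape[1]))
    return len(coords) / hull_pixels


# ---------------------------------------------------------------------
# fixed polyomino enumeration (translation-normalized)
# ---------------------------------------------------------------------

def polyominoes(max_cells: int):
    """All fixed polyominoes with up to ``max_cells`` cells."""
    current = {frozenset([(0, 0)])}
    seen = set(current)
    yield from current
    for _ in range(max_cells - 1):
        grown = set()
        for poly in current:
            for (r, c) in poly:
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    cell = (r + dr, c + dc)
                    if cell in poly:
                        continue
                    new = poly | {cell}
                    rmin = min(r for r, _ in new)
                    cmin = min(c for _, c in new)
                    norm = frozenset((r - rmin, c - cmin) for r, c in new)
                    if norm not in seen:
                        seen.add(norm)
                        grown.add(norm)
        yield from grown
        current = grown


def polyomino_mask(poly) -> np.ndarray:
    rmax = max(r for r, _ in poly)
    cmax = max(c for _, c in poly)
    mask = np.zeros((rmax + 1, cmax + 1), dtype=bool)
    for r, c in poly:
        mask[r, c] = True
    return mask


# ---------------------------------------------------------------------
# AND-with-restore via explicit flood fill
# ---------------------------------------------------------------------

def restore_oracle(y: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Flood-fill (8-neighborhood) every y component from seeds in y∧m."""
    y = np.asarray(y, dtype=bool)
    m = np.asarray(m, dtype=bool)
    out = np.zeros_like(y)
    H, W = y.shape
    stack = [(r, c) for r in range(H) for c in range(W) if y[r, c] and m[r, c]]
    for seed in stack:
        if out[seed]:
            continue
        frontier = [seed]
        out[seed] = True
        while frontier:
            r, c = frontier.pop()
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < H and 0 <= cc < W and y[rr, cc]
                            and not out[rr, cc]):
                        out[rr, cc] = True
                        frontier.append((rr, cc))
    return out


def fuse_oracle(y, m, c, custom):
    return restore_oracle(y, m) | np.asarray(c, bool) | np.asarray(custom, bool)


# ---------------------------------------------------------------------
# count-pair metric tally, one pair at a time
# ---------------------------------------------------------------------

def metrics_oracle(pairs):
    tp = fp = fn = 0
    devs = []
    for est, tru in pairs:
        tp += min(est, tru)
        fp += max(0, est - tru)
        fn += max(0, tru - est)
        devs.append(est - tru)
    precision = 100.0 * tp / (tp + fp) if tp + fp else 0.0
    recall = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {
        "precision": precision, "recall": recall, "f1": f1,
        "mean_deviation": sum(devs) / len(devs),
        "mean_abs_deviation": sum(abs(d) for d in devs) / len(devs),
        "min_deviation": min(devs), "max_deviation": max(devs),
    }


# ---------------------------------------------------------------------
# pseudo-CIELAB custom channel from first principles
# ---------------------------------------------------------------------

def custom_channel_oracle(r: int, g: int, b: int) -> int:
    """Third sRGB channel of Lab→RGB applied to (R,G,B) read as (L,a,b).

    L = R·100/255, a = G−128, b = B−128; D65 white point; sRGB
    companding; result clipped to [0,255]."""
    L = r * 100.0 / 255.0
    a = g - 128.0
    bb = b - 128.0
    fy = (L + 16.0) / 116.0
    fx = fy + a / 500.0
    fz = fy - bb / 200.0
    delta = 6.0 / 29.0

    def finv(t):
        return t ** 3 if t > delta else 3 * delta ** 2 * (t - 4.0 / 29.0)

    xn, yn, zn = 0.95047, 1.0, 1.08883
    x, y, z = xn * finv(fx), yn * finv(fy), zn * finv(fz)
    blue_lin = 0.0557 * x - 0.2040 * y + 1.0572 * z
    if blue_lin <= 0.0031308:
        blue = 12.92 * blue_lin
    else:
        blue = 1.055 * blue_lin ** (1 / 2.4) - 0.055
    return int(round(max(0.0, min(1.0, blue)) * 255.0))
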