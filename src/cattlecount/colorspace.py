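"""Quadrant-wise color-space decomposition and binary mask generation.

The region of interest is split into four quadrants so illumination can
be normalized locally: each quadrant gets a brightness correction factor
cf = 85 / mean(pixel values). Four channels are derived per quadrant —
C, M, Y of the CMYK decomposition (K is discarded) plus a "custom"
channel obtained by applying the CIELAB→RGB formulas to the RGB values
as if they were L, a, b. In every channel the animals are darker than
their surroundings, so binarization marks pixels *below* the threshold
white. C, M and custom use fixed or cf-scaled thresholds; Y uses a
histogram-valley rule per quadrant, and the smallest valid quadrant
threshold is applied globally at T, T/2 and T/4, yielding three Y masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage import color as skcolor

from .config import RunConfig
from .roi import RoiImage


class UndefinedCfError(ValueError):
    """Correction factor undefined: the quadrant has no ROI pixels."""


class DegenerateInputError(ValueError):
    pass


@dataclass
class Quadrant:
    """One quarter of the ROI image (half-open pixel window)."""

    index: int                            # 0=TL, 1=TR, 2=BL, 3=BR
    window: tuple[int, int, int, int]     # (r0, r1, c0, c1)
    pixels: np.ndarray                    # view into the ROI pixels
    roi_mask: np.ndarray                  # view into the ROI mask

    @property
    def active(self) -> bool:
        return bool(self.roi_mask.any())


@dataclass
class ChannelSet:
    C: np.ndarray
    M: np.ndarray
    Y: np.ndarray
    custom: np.ndarray


@dataclass(frozen=True)
class YThresholdResult:
    status: str                           # dark | valid | discarded
    threshold: Optional[int] = None       # bin index when not discarded


@dataclass
class MaskSet:
    """The six reassembled binary masks (white = candidate animal).

    The three Y masks use the global threshold T, T/2 and T/4; since
    white means value < threshold, they nest as
    ``y_quarter ⊆ y_half ⊆ y_full``.
    """

    c: np.ndarray
    m: np.ndarray
    y_full: np.ndarray
    y_half: np.ndarray
    y_quarter: np.ndarray
    custom: np.ndarray
    global_y_threshold: Optional[int]
    y_valid: bool                         # some quadrant produced a threshold
    any_active: bool
    quadrant_log: list[dict] = field(default_factory=list)

    def y_masks(self) -> dict[str, np.ndarray]:
        return {"full": self.y_full, "half": self.y_half,
                "quarter": self.y_quarter}


# ---------------------------------------------------------------------
# quadrants
# ---------------------------------------------------------------------

def split_quadrants(roi: RoiImage) -> list[Quadrant]:
    """Partition the image into four quadrants.

    For odd dimensions the top/left windows take the extra row/column.
    """
    H, W = roi.shape
    if H < 2 or W < 2:
        raise DegenerateInputError(f"cannot split a {H}x{W} image")
    rs = -(-H // 2)     # ceil
    cs = -(-W // 2)
    windows = [(0, rs, 0, cs), (0, rs, cs, W),
               (rs, H, 0, cs), (rs, H, cs, W)]
    return [Quadrant(index=i, window=w,
                     pixels=roi.pixels[w[0]:w[1], w[2]:w[3]],
                     roi_mask=roi.roi_mask[w[0]:w[1], w[2]:w[3]])
            for i, w in enumerate(windows)]


def correction_factor(q: Quadrant, target_mean: float = 85.0) -> float:
    """cf = 85 / mean of pixel values over all three channels.

    The mean runs over ROI pixels only — tiles zeroed during ROI
    extraction would deflate it meaninglessly.
    """
    if not q.roi_mask.any():
        raise UndefinedCfError("all-ROI-zero quadrant has no defined cf")
    mean = float(q.pixels[q.roi_mask].mean())
    if mean == 0.0:
        raise UndefinedCfError("quadrant mean is zero")
    return target_mean / mean


# ---------------------------------------------------------------------
# channels
# ---------------------------------------------------------------------

def decompose_channels(pixels: np.ndarray) -> ChannelSet:
    """C, M, Y of the CMYK decomposition plus the custom pseudo-CIELAB
    channel, each rescaled to 8-bit.

    CMYK uses standard black extraction: K' = 1 - max(R,G,B)/255 and
    C = (1 - R/255 - K')/(1 - K'); pure black maps to C=M=Y=0. The
    custom channel feeds (L, a, b) = (R·100/255, G-128, B-128) through
    the CIELAB→sRGB formulas (D65, sRGB companding) and keeps the third
    output channel scaled back to [0, 255].
    """
    rgb = pixels.astype(np.float32)
    mx = rgb.max(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        cmy = np.where(mx[..., None] > 0,
                       255.0 * (mx[..., None] - rgb) / mx[..., None],
                       0.0)
    cmy = np.clip(np.rint(cmy), 0, 255).astype(np.uint8)

    lab = np.empty_like(rgb)
    lab[..., 0] = rgb[..., 0] * (100.0 / 255.0)
    lab[..., 1] = rgb[..., 1] - 128.0
    lab[..., 2] = rgb[..., 2] - 128.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # out-of-gamut values are expected
        pseudo = skcolor.lab2rgb(lab)
    custom = np.clip(np.rint(pseudo[..., 2] * 255.0), 0, 255).astype(np.uint8)
    return ChannelSet(C=cmy[..., 0], M=cmy[..., 1], Y=cmy[..., 2],
                      custom=custom)


def fixed_thresholds(cf: float, config: RunConfig = RunConfig()
                     ) -> tuple[float, float, float]:
    """Binarization thresholds for the C, M and custom channels.

    tC = min(100, 40·cf); tM = 30; tCustom = min(150, 120·cf).
    """
    if cf <= 0:
        raise ValueError("correction factor must be positive")
    t_c = min(config.c_threshold_cap, config.c_threshold_scale * cf)
    t_custom = min(config.custom_threshold_cap,
                   config.custom_threshold_scale * cf)
    return t_c, config.m_threshold, t_custom


# ---------------------------------------------------------------------
# Y-channel histogram-valley threshold
# ---------------------------------------------------------------------

def smooth_histogram(hist: np.ndarray, window: int = 25) -> np.ndarray:
    """Centered moving average with reflected boundaries.

    Window sums are accumulated in integer arithmetic so that equal-mass
    windows compare exactly equal — peak and valley decisions on count
    histograms must not depend on float accumulation order.
    """
    h = np.rint(np.asarray(hist, dtype=np.float64)).astype(np.int64)
    pad = window // 2
    padded = np.pad(h, pad, mode="symmetric")
    sums = np.convolve(padded, np.ones(window, dtype=np.int64), mode="valid")
    return sums / window


def _find_peaks(sm: np.ndarray) -> list[int]:
    """Strict local maxima; plateaus report their leftmost bin."""
    peaks = []
    n = len(sm)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sm[j + 1] == sm[i]:
            j += 1
        left_ok = i > 0 and sm[i - 1] < sm[i]
        right_ok = j < n - 1 and sm[j + 1] < sm[i]
        if left_ok and right_ok:
            peaks.append(i)
        i = j + 1
    return peaks


def _merge_close_peaks(peaks: list[int], sm: np.ndarray,
                       min_sep: int) -> list[int]:
    """Drop the smaller of any two peaks closer than ``min_sep`` bins.

    Ties keep the lower-index peak. Repeats until stable.
    """
    peaks = sorted(peaks)
    changed = True
    while changed:
        changed = False
        for i in range(len(peaks) - 1):
            if peaks[i + 1] - peaks[i] < min_sep:
                if sm[peaks[i + 1]] > sm[peaks[i]]:
                    del peaks[i]
                else:
                    del peaks[i + 1]
                changed = True
                break
    return peaks


def y_threshold_from_histogram(hist: np.ndarray,
                               config: RunConfig = RunConfig()
                               ) -> YThresholdResult:
    """Full Y-threshold rule chain on a 256-bin histogram.

    Smooth (window 25) → dark test (mass of the first 10 bins vs the top
    156 bins → threshold 10) → peak finding → merge peaks closer than 30
    bins → need ≥2 peaks (else discarded) → keep the two lowest-index
    peaks → among inter-peak bins with amplitude below 10% of the second
    peak, take the one closest to the second peak; fall back to the
    inter-peak minimum.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if hist.shape != (256,):
        raise DegenerateInputError("expected a 256-bin histogram")
    if hist.sum() == 0:
        raise DegenerateInputError("empty histogram")
    sm = smooth_histogram(hist, config.smooth_window)
    low = sm[:config.dark_low_bins].sum()
    high = sm[256 - config.dark_high_bins:].sum()
    if low > high:
        return YThresholdResult(status="dark", threshold=config.dark_threshold)
    peaks = _merge_close_peaks(_find_peaks(sm), sm,
                               config.peak_min_separation)
    if len(peaks) < 2:
        return YThresholdResult(status="discarded")
    p1, p2 = peaks[0], peaks[1]
    amp = config.valley_fraction * sm[p2]
    candidates = [j for j in range(p1 + 1, p2) if sm[j] < amp]
    if candidates:
        thr = max(candidates)            # closest to the second peak
    else:
        between = sm[p1 + 1:p2]
        thr = p1 + 1 + int(np.argmin(between))
    return YThresholdResult(status="valid", threshold=int(thr))


def y_quadrant_threshold(y: np.ndarray, roi_mask: Optional[np.ndarray] = None,
                         config: RunConfig = RunConfig()) -> YThresholdResult:
    """Apply the Y-threshold rule chain to a quadrant's Y channel."""
    values = y[roi_mask] if roi_mask is not None else y.ravel()
    if values.size == 0:
        raise DegenerateInputError("no ROI pixels in quadrant")
    hist = np.bincount(values.astype(np.uint8), minlength=256)[:256]
    return y_threshold_from_histogram(hist, config)


# ---------------------------------------------------------------------
# full mask-set assembly
# ---------------------------------------------------------------------

def build_mask_set(roi: RoiImage, config: RunConfig = RunConfig()) -> MaskSet:
    """Steps (2)–(8): quadrants, cf, channels, thresholds, reassembly.

    Quadrants whose Y channel has fewer than ``min_active_pixels``
    nonzero pixels are discarded and contribute all-black regions to
    every mask. The global Y threshold is the minimum over quadrant
    thresholds with status ``dark`` or ``valid``.
    """
    H, W = roi.shape
    quads = split_quadrants(roi)
    shape = (H, W)
    masks = {k: np.zeros(shape, dtype=bool)
             for k in ("c", "m", "custom")}
    kept: list[tuple[Quadrant, ChannelSet]] = []
    y_thresholds: list[int] = []
    log: list[dict] = []
    any_active = False

    for q in quads:
        entry: dict = {"quadrant": q.index, "window": q.window}
        if not q.active:
            entry["status"] = "inactive"
            log.append(entry)
            continue
        any_active = True
        channels = decompose_channels(q.pixels)
        n_active = int(((channels.Y > 0) & q.roi_mask).sum())
        entry["active_y_pixels"] = n_active
        if n_active < config.min_active_pixels:
            entry["status"] = "too_little_content"
            log.append(entry)
            continue
        cf = correction_factor(q, config.target_mean)
        t_c, t_m, t_custom = fixed_thresholds(cf, config)
        r0, r1, c0, c1 = q.window
        masks["c"][r0:r1, c0:c1] = (channels.C < t_c) & q.roi_mask
        masks["m"][r0:r1, c0:c1] = (channels.M < t_m) & q.roi_mask
        masks["custom"][r0:r1, c0:c1] = (channels.custom < t_custom) & q.roi_mask
        y_res = y_quadrant_threshold(channels.Y, q.roi_mask, config)
        entry.update(status="kept", cf=cf, t_c=t_c, t_m=t_m,
                     t_custom=t_custom, y_status=y_res.status,
                     y_threshold=y_res.threshold)
        log.append(entry)
        kept.append((q, channels))
        if y_res.status in ("dark", "valid"):
            y_thresholds.append(int(y_res.threshold))

    t_global: Optional[int] = min(y_thresholds) if y_thresholds else None
    y_masks = {v: np.zeros(shape, dtype=bool)
               for v in ("full", "half", "quarter")}
    if t_global is not None:
        variants = {"full": t_global, "half": t_global // 2,
                    "quarter": t_global // 4}
        for q, channels in kept:
            r0, r1, c0, c1 = q.window
            for name, thr in variants.items():
                y_masks[name][r0:r1, c0:c1] = (channels.Y < thr) & q.roi_mask

    return MaskSet(c=masks["c"], m=masks["m"], y_full=y_masks["full"],
                   y_half=y_masks["half"], y_quarter=y_masks["quarter"],
                   custom=masks["custom"], global_y_threshold=t_global,
                   y_valid=t_global is not None, any_active=any_active,
                   quadrant_log=log)
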